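# Methods

This note records the models implemented in `mixt`, the parameter defaults
and why they hold, the numerical conventions, and what the synthetic-data
tests do and do not demonstrate.

## Co-expression networks and modules

**Model.** A module is a set of genes sharing one latent expression
pattern across samples within a tissue. Networks are *unsigned*: the
similarity between genes i and j is |Pearson correlation| over matched
patients (controls never enter network construction), soft-thresholded to
the adjacency `a_ij = |s_ij|^β`. The topological overlap

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    k_i = Σ_{u≠i} a_iu,   TOM_ii = 1,

measures direct plus shared-neighbor connectivity; `1 − TOM` is the
clustering dissimilarity. Pearson is the default correlation (Spearman is
a config option); β = 6 is the conventional unsigned default.

**Branch cutting.** Modules are branches of the average-linkage dendrogram
of `1 − TOM`. The implementation is a simplified dynamic-hybrid procedure:

1. *Adaptive cut height.* Merge heights of a structured TOM dendrogram
   split into a low band (within-branch merges) and a high band
   (between-branch and background joins). The cut is placed at the
   midpoint of the widest gap between consecutive sorted merge heights in
   the upper half of the height distribution. `deep_split` (default 2)
   selects among the qualifying gaps (those at least 20% as wide as the
   widest), with higher values taking lower gaps and hence finer branches.
2. *Size filter.* Flat clusters under `min_module_size` (default 30)
   become `grey`.
3. *PAM-like rescue.* Each grey gene joins the module with the smallest
   mean TOM-dissimilarity to its members, provided that distance lies
   within the module's internal spread (mean + 1 sd of within-module
   dissimilarities). Genes far from every module — pure noise — stay grey.
4. *Eigengene merge.* A module's eigengene is the first principal
   component over samples of its gene-standardized expression,
   sign-oriented so the mean gene–eigengene correlation is positive.
   While any two module eigengenes correlate above `merge_threshold`
   (default 0.75), the most-correlated pair is merged and eigengenes
   recomputed; the loop is deterministic and idempotent.
5. *Relabeling* by decreasing size over the standard color palette;
   `grey` is reserved for unassigned genes and excluded downstream.

This is deliberately simpler than the full dynamic-hybrid algorithm; the
contract is behavioral, enforced by the planted-recovery tests: exact
recovery of orthogonal blocks, noise genes left grey, over-split blocks
reunited by the merge step, gene-order invariance, and ARI ≥ 0.8 on the
standard scenario (in practice ARI = 1.0). On data with weak, highly
nested module structure the cut-height heuristic will behave differently
from the reference algorithm; the parameters are exposed for tuning.

Edge export keeps pairs with TOM strictly above 0.1 and drops isolated
nodes.

## Ranksum ordering and the Region of Independence

Each module gene ranks the reference samples ascending with average ties,
so every gene contributes ranks summing to n(n+1)/2 and the per-sample
ranksum over k genes lies in [k, k·n] (total fixed at k·n(n+1)/2 — a
conservation law the tests assert). Displays order patients by descending
ranksum left-to-right; stored data is always the raw ranksum.

ROI bounds are the central-95% empirical quantiles (linear interpolation)
of 10,000 null ranksums, each the sum of k independent uniform ranks in
{1..n}. Independent uniform ranks — rather than permutations of the
observed, possibly tied rank vectors — are the default because averaged
ties make the observed marginals near-uniform anyway; a per-gene
permutation variant is available. Bounds are inclusive: a ranksum exactly
at a bound is `mid`, the conservative call. With a fixed seed the bounds
are bit-reproducible; across seeds they move by well under 1% of the
attainable range at 10,000 draws.

Controls (blood-only samples) are placed on a patient-derived profile by
ranking them jointly with the patients and rescaling the patient ROI
bounds affinely from [k, k·n] to [k, k·n_joint]. The profile itself is
always defined on patients only. This placement is a documented package
choice; nothing upstream constrains it.

Gene orientation is the sign of the Pearson correlation between a member
gene and the ranksum vector; exact zero maps to + by convention.

## Association testing

Continuous attributes: Pearson r between ranksum and attribute, permuted
two-sided via |r|. Categorical: one-way ANOVA F. Empirical p uses add-one
smoothing, `p = (1 + #{perm ≥ obs}) / (1 + B)` with B = 1000 by default,
so p is never 0 and never below 1/(B+1); ties at the observed statistic
count as exceedances (≥ with a 1e-12 guard against float noise). Missing
attribute values are dropped per test. Subtype indicators are tested
one-vs-rest (binary ANOVA ≡ t-test), and levels with fewer than 11
observations are skipped. FDR is Benjamini–Hochberg within one family per
clinical variable across all modules of both tissues; closely related
variables can be declared as one family in the config.

Per-test seeds are derived by stable hashing (blake2b) of the master seed
and the test identifiers, so any single test is reproducible in isolation
and independent of scan order.

## Cross-tissue interactions

The MIxT statistic for a (tumor module, blood module) pair is the Pearson
correlation of their ranksum vectors over the matched patients of a
stratum. The null permutes the patient matching within the stratum for
one tissue — preserving each tissue's marginal ranksum distribution while
breaking the link — with B = 10,000 permutations by default and the same
two-sided add-one p. Calls use a fixed α = 0.005 with no cross-stratum
multiplicity correction (a global BH pass can be applied to the output
table); direction is reported separately. Strata need more than 10
patients (`min_stratum = 11`); smaller ones are skipped and logged. The
statistic is symmetric in the two tissues.

The all-pairs *background distribution* caller — the observed r of every
module pair within a stratum, with empirical 2.5%/97.5% bounds — is
implemented as an alternative and reported separately; per-pair
permutation is the default because it yields a calibrated p-value for
each pair rather than a position in a mixture of nulls and signals.

Gene-composition overlap across tissues is a one-sided (enrichment)
hypergeometric test on the shared gene universe (the intersection of the
two tissues' gene lists — per-tissue networks keep each tissue's full
list), BH over all module pairs, significant at fdr < 0.01.

## Enrichment

For subset size n, set size K, universe N and overlap x, the p-value sums
hypergeometric probabilities of all overlap outcomes whose likelihood does
not exceed pmf(x) (relative tolerance 1e-9 so float noise cannot drop
exact ties). At the modal overlap p = 1; for over-represented overlaps it
reduces to the one-sided upper tail. p is exchangeable in (set, subset).
Subsets tested per module: all members, ranksum-positive (up),
ranksum-negative (dn); empty subsets are skipped with a log entry. FDR is
per collection × subset. The universe defaults to the tissue's network
genes. GO-specific elimination algorithms are out of scope; GO terms
supplied as a flat GMT are tested by the same procedure, which ignores the
ontology graph.

## Synthetic cohorts

Gene g in module m of tissue t is `x = s_g·λ·f_{m,t} + ε` with standard
normal factors f, `ε ~ N(0, σ)`, sign s_g negative for a configured
fraction of members (default 0.2), and `λ = sqrt(c/(1−c))·σ` so the
expected within-module |correlation| is exactly the target c. Planted
interactions draw the two factors bivariate-normal with correlation ρ for
the stratum's patients and independently elsewhere; controls draw baseline
blood factors. Subtype labels are assigned independently of all factors
(exact counts or probabilities per level), so null calibration is exact by
construction; continuous covariates may be linked to a factor. Module
membership within each tissue is an independent random permutation of a
shared gene namespace, making cross-tissue gene overlap hypergeometric by
construction. One seed drives everything; regeneration is bit-identical.

**Standard scenarios** (package defaults, used by tests and the
acceptance script):

- *Demo / determinism*: 120 patients, 40 controls, 1,000 genes and 6
  modules (sizes 150/120/100/80/60/40, c = 0.6) per tissue, two planted
  interactions (ρ = ±0.7) in strata of 40.
- *Module recovery*: 5 × 100-gene modules, c = 0.6, n = 150, 3 seeds.
- *Interaction power*: ρ = 0.7 in a stratum of exactly 40 patients,
  4 × 100-gene modules per tissue, 100 replicates.
- *Null calibration*: 12 × 60-gene modules per tissue, two 3-level
  schemes, no interactions; 10 cohorts × 1,008 pair tests ≥ 10,000 tests.

Permutation counts in the large scans use B = 1,999 (p-resolution
5·10⁻⁴, ample at α = 0.005); single-pair analyses default to B = 10,000.

**What the generator does not emulate:** probe/batch effects,
missingness, heavy-tailed or count-scale expression, correlated modules
within a tissue, overlapping module membership, and subtype-dependent
module strength. Passing recovery tests therefore shows the estimators
are correct and calibrated under the latent-factor model, not that module
detection is robust to real microarray artifacts — the preprocessing that
would address those lives upstream of this package.

## Numerical conventions and degenerate inputs

- Correlation matrices are symmetrized, clipped to [−1, 1], unit diagonal;
  exact-constant genes (zero range) are rejected by name.
- TOM is computed with the diagonal excluded from connectivities, then
  symmetrized and clipped to [0, 1].
- Quantiles use linear interpolation between order statistics.
- Permutation exceedance uses ≥ with an absolute 1e-12 tie guard.
- Ranksum with all-tied expression (e.g. a zero-noise cohort) yields the
  average rank everywhere; downstream tests that require non-constant
  ranksums skip such modules with a logged reason rather than failing.
- PAM-stage ties and merge-order ties break lexicographically, making
  module detection invariant to gene ordering.
- All result tables are TSV with a schema-version comment; reruns with the
  same config and seed are byte-identical.

## Known limitations

- The branch-cutting heuristic targets well-separated factor modules; the
  reference dynamic-hybrid algorithm handles nested/weak structure better.
- The eigengene merge recomputes a full correlation pass per merge —
  quadratic in module count, irrelevant below a few hundred modules.
- Dense TOM computation is O(n³)/O(n²) memory; fine to ~20k genes on a
  workstation but not block-decomposed.
- Control placement on patient orderings (joint ranking + affine bound
  rescale) is one defensible convention among several.
- The acceptance power/calibration numbers are properties of the standard
  scenarios above; other effect sizes or stratum sizes scale as usual
  power analysis predicts.
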