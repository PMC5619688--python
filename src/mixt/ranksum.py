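"""Ranksum sample ordering, the Region of Independence, and gene orientation.

Each gene of a module ranks the reference samples by expression (ascending,
ties averaged); a sample's ranksum is the sum of its ranks over the module's
k genes, which induces a linear ordering of the cohort.  The Region of
Independence (ROI_95) is delimited by Monte-Carlo "artificial patients"
whose per-gene ranks are independently randomized: the interval containing
95% of their ranksums.  Samples below it are "low", above it "high", inside
it "mid" — mid samples are those in which the module's genes have lost
their coordinated expression.  Renderings conventionally place high-ranksum
samples on the left; stored data is always the raw ranksum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

CATEGORIES = ("low", "mid", "high")


@dataclass
class RanksumProfile:
    """Per-module linear ordering of samples with ROI bounds and categories."""

    tissue: str
    module: str
    genes: list
    ranksum: pd.Series          # per reference sample
    roi_low: float
    roi_high: float
    category: pd.Series         # per reference sample, in {low, mid, high}
    gene_orientation: pd.Series  # per member gene, +1 / -1
    n_draws: int
    level: float
    seed: int

    @property
    def k(self) -> int:
        return len(self.genes)

    @property
    def n(self) -> int:
        return len(self.ranksum)

    def ordered_samples(self) -> list:
        """Display ordering: descending ranksum left-to-right."""
        return list(self.ranksum.sort_values(ascending=False, kind="mergesort").index)


def compute_ranksum(expr, genes, reference_samples=None) -> pd.Series:
    """Per-sample sum of within-cohort expression ranks over the given genes.

    Ranks are ascending with ties averaged, so each gene's ranks sum to
    n(n+1)/2 and the ranksum lives in [k, k*n].
    """
    genes = list(genes)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if reference_samples is None:
        reference_samples = expr.patient_samples
    reference_samples = pd.Index(reference_samples)
    if len(reference_samples) < 3:
        raise ValueError(f"need >=3 reference samples, got {len(reference_samples)}")
    missing = [g for g in genes if g not in expr.gene_ids]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing[:5]}")
    x = expr.values.loc[genes, reference_samples].to_numpy(dtype=float)
    ranks = rankdata(x, axis=1)
    return pd.Series(ranks.sum(axis=0), index=reference_samples, name="ranksum")


def compute_roi(n_samples: int, k: int, n_draws: int = 10_000,
                level: float = 0.95, seed: int = 0,
                method: str = "uniform", observed_ranks=None):
    """ROI bounds from Monte-Carlo null ranksums.

    Each draw sums k independently randomized ranks: by default i.i.d.
    uniform integers in {1..n} per gene ("uniform"); with
    ``method="permutation"`` each gene contributes a draw from its observed
    (tie-averaged) rank vector instead.  Bounds are the central
    ``level``-probability empirical quantiles (linear interpolation).
    """
    if n_samples < 3 or k < 1:
        raise ValueError("need n_samples >= 3 and k >= 1")
    if n_draws < 100:
        raise ValueError(f"n_draws={n_draws} too small for stable quantiles")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    if method == "uniform":
        draws = rng.integers(1, n_samples + 1, size=(n_draws, k)).sum(axis=1)
    elif method == "permutation":
        if observed_ranks is None:
            raise ValueError("method='permutation' requires observed_ranks (k x n)")
        obs = np.asarray(observed_ranks, dtype=float)
        idx = rng.integers(0, obs.shape[1], size=(n_draws, obs.shape[0]))
        draws = np.take_along_axis(obs.T, idx, axis=0).sum(axis=1)
    else:
        raise ValueError(f"unknown ROI method {method!r}")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha], method="linear")
    return float(lo), float(hi)


def categorize(ranksum: pd.Series, roi_low: float, roi_high: float) -> pd.Series:
    """low / mid / high per sample; ROI bounds are inclusive (boundary = mid)."""
    if roi_low > roi_high:
        raise ValueError("roi_low must not exceed roi_high")
    vals = ranksum.to_numpy(dtype=float)
    cat = np.where(vals < roi_low, "low", np.where(vals > roi_high, "high", "mid"))
    return pd.Series(cat, index=ranksum.index, name="category")


def orient_genes(expr, genes, ranksum: pd.Series) -> pd.Series:
    """Sign of each member gene's Pearson correlation with the ranksum vector.

    Zero correlation maps to +1 by convention.  The red/blue sidebars of the
    module heatmaps are exactly these signs.
    """
    genes = list(genes)
    rs = ranksum.to_numpy(dtype=float)
    if np.ptp(rs) == 0:
        raise ValueError("constant ranksum: gene orientation undefined")
    x = expr.values.loc[genes, ranksum.index].to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    rc = rs - rs.mean()
    cors = (xc @ rc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(rc) + 1e-300)
    signs = np.where(cors >= 0, 1, -1)
    return pd.Series(signs, index=pd.Index(genes, name="gene"), name="orientation")


def build_profile(expr, module: str, genes, reference_samples=None,
                  n_draws: int = 10_000, level: float = 0.95,
                  seed: int = 0, roi_method: str = "uniform") -> RanksumProfile:
    """Full ranksum profile for one module: ordering, ROI, categories, signs."""
    rs = compute_ranksum(expr, genes, reference_samples)
    roi_low, roi_high = compute_roi(
        n_samples=len(rs), k=len(list(genes)), n_draws=n_draws,
        level=level, seed=seed, method=roi_method,
    )
    return RanksumProfile(
        tissue=expr.tissue,
        module=module,
        genes=list(genes),
        ranksum=rs,
        roi_low=roi_low,
        roi_high=roi_high,
        category=categorize(rs, roi_low, roi_high),
        gene_orientation=orient_genes(expr, genes, rs),
        n_draws=n_draws,
        level=level,
        seed=seed,
    )


def profiles_for_modules(expr, module_set, reference_samples=None,
                         n_draws: int = 10_000, level: float = 0.95,
                         master_seed: int = 0) -> dict:
    """Ranksum profiles for every named module of a tissue (grey excluded).

    Per-module seeds are derived from the master seed so single profiles are
    reproducible in isolation.
    """
    from ._util import derive_seed

    out = {}
    for module, genes in module_set.modules().items():
        out[module] = build_profile(
            expr, module, genes, reference_samples=reference_samples,
            n_draws=n_draws, level=level,
            seed=derive_seed(master_seed, "roi", module_set.tissue, module),
        )
    return out


def score_extra_samples(profile: RanksumProfile, expr, extra_samples) -> tuple:
    """Place additional samples (e.g. blood controls) on a patient profile.

    The extras are ranked jointly with the reference cohort; the patient-only
    ROI bounds are rescaled affinely from the attainable range [k, k*n] to
    [k, k*n_joint] before categorizing.  The profile itself (defined on
    patients only) is unchanged.
    """
    extra_samples = pd.Index(extra_samples)
    joint = profile.ranksum.index.append(extra_samples)
    rs_joint = compute_ranksum(expr, profile.genes, joint)
    k, n, nj = profile.k, profile.n, len(joint)
    scale = (nj - 1) / (n - 1)
    lo = k + (profile.roi_low - k) * scale
    hi = k + (profile.roi_high - k) * scale
    return rs_joint, categorize(rs_joint, lo, hi)
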