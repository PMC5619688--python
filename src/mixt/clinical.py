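"""Module–attribute association tests and mean-expression signature scores.

A module's ranksum vector is tested against each clinical attribute:
Pearson correlation for continuous attributes (age, weight, MKS, LUMS,
HER2S, ...) and one-way ANOVA for categorical ones (ER, HER2, subtype
labels, lymph-node status, ...).  Empirical p-values come from permuting
the clinical labels (B=1000 by default) with the two-sided statistic |r|
for Pearson and F for ANOVA, smoothed as (1 + #{perm >= obs}) / (1 + B).
FDR is controlled by Benjamini–Hochberg within one family per clinical
variable (all modules of both tissues together), with user-declared
groupings available for families of very similar variables.

Signature scores (HER2S, LUMS, MKS, or user-defined) are arithmetic means
of member-gene expression per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._util import derive_seed, log


@dataclass
class SignatureScore:
    name: str
    genes: list            # genes actually used (present in the matrix)
    score: pd.Series       # per sample


@dataclass
class ModuleClinicalAssociation:
    tissue: str
    module: str
    attribute: str
    test: str              # "pearson" | "anova"
    statistic: float       # r or F
    p_param: float
    p_emp: float
    n_used: int
    B: int
    seed: int


def signature_score(expr, genes, name: str) -> SignatureScore:
    """Per-sample mean expression over the listed genes.

    Genes absent from the matrix are dropped with a warning; an empty
    intersection is an error.
    """
    genes = list(genes)
    present = [g for g in genes if g in expr.gene_ids]
    missing = [g for g in genes if g not in expr.gene_ids]
    if not present:
        raise ValueError(f"signature {name!r}: none of its genes are in the matrix")
    if missing:
        log.warning("signature %s: %d/%d genes missing from matrix (%s...)",
                    name, len(missing), len(genes), missing[:3])
    score = expr.values.loc[present].mean(axis=0)
    score.name = name
    return SignatureScore(name=name, genes=present, score=score)


def _perm_pearson(x: np.ndarray, y: np.ndarray, B: int, rng) -> tuple:
    r, p = stats.pearsonr(x, y)
    xs = (x - x.mean()) / (x.std() + 1e-300)
    ys = (y - y.mean()) / (y.std() + 1e-300)
    perms = np.argsort(rng.random((B, len(y))), axis=1)
    r_perm = (ys[perms] @ xs) / len(x)
    p_emp = (1.0 + np.count_nonzero(np.abs(r_perm) >= abs(r) - 1e-12)) / (1.0 + B)
    return float(r), float(p), float(p_emp)


def _anova_f(x: np.ndarray, codes: np.ndarray, n_levels: int) -> float:
    """One-way ANOVA F for x grouped by integer codes (vector form)."""
    n = len(x)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    sums = np.bincount(codes, weights=x, minlength=n_levels)
    grand = x.mean()
    ss_between = np.sum(sums**2 / counts) - n * grand**2
    ss_total = np.sum(x**2) - n * grand**2
    ss_within = ss_total - ss_between
    df_b, df_w = n_levels - 1, n - n_levels
    if df_w <= 0 or ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def _perm_anova(x: np.ndarray, labels: np.ndarray, B: int, rng) -> tuple:
    levels, codes = np.unique(labels, return_inverse=True)
    groups = [x[codes == i] for i in range(len(levels))]
    f_obs, p = stats.f_oneway(*groups)
    perms = np.argsort(rng.random((B, len(x))), axis=1)
    f_perm = np.array([_anova_f(x[perm], codes, len(levels)) for perm in perms])
    p_emp = (1.0 + np.count_nonzero(f_perm >= f_obs - 1e-12)) / (1.0 + B)
    return float(f_obs), float(p), float(p_emp)


def associate(ranksum: pd.Series, attribute: pd.Series, kind: str,
              B: int = 1000, seed: int = 0, tissue: str = "", module: str = "",
              ) -> ModuleClinicalAssociation:
    """Test one module ranksum against one clinical attribute.

    ``kind`` is "continuous" (Pearson, two-sided via |r| permutations) or
    "categorical" (one-way ANOVA F permutations).  Samples with a missing
    attribute are dropped for this test only.
    """
    joined = pd.concat([ranksum.rename("rs"), attribute.rename("attr")],
                       axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError(f"<3 usable samples for {attribute.name!r}")
    x = joined["rs"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    if kind == "continuous":
        y = joined["attr"].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise ValueError(f"constant attribute {attribute.name!r}")
        stat, p, p_emp = _perm_pearson(y, x, B, rng)
        test = "pearson"
    elif kind == "categorical":
        labels = joined["attr"].astype(str).to_numpy()
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) < 2:
            raise ValueError(f"constant attribute {attribute.name!r}")
        if (counts < 2).any():
            raise ValueError(
                f"attribute {attribute.name!r}: level with <2 samples")
        stat, p, p_emp = _perm_anova(x, labels, B, rng)
        test = "anova"
    else:
        raise ValueError(f"unknown attribute kind {kind!r}")
    return ModuleClinicalAssociation(
        tissue=tissue, module=module, attribute=str(attribute.name), test=test,
        statistic=stat, p_param=p, p_emp=p_emp, n_used=len(joined), B=B, seed=seed,
    )


def fdr_adjust(pvals, family_ids) -> np.ndarray:
    """Benjamini–Hochberg FDR within each declared family."""
    pvals = np.asarray(pvals, dtype=float)
    if ((pvals < 0) | (pvals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    fam = np.asarray(family_ids)
    out = np.empty_like(pvals)
    for f in np.unique(fam):
        mask = fam == f
        out[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    return out


def associate_all(profiles: dict, clinical, attributes=None, B: int = 1000,
                  master_seed: int = 0, families=None,
                  one_vs_rest: tuple = (), min_level_size: int = 11) -> pd.DataFrame:
    """Association table for every (module, attribute) pair, BH per family.

    ``profiles`` maps tissue → {module → RanksumProfile}.  By default every
    clinical variable is its own FDR family spanning all modules of both
    tissues; ``families`` (attribute → family name) groups very similar
    variables.  Attributes listed in ``one_vs_rest`` are expanded into
    binary indicator tests per level (level vs rest), skipping levels with
    n <= ``min_level_size - 1`` observations.
    """
    rows = []
    attrs = list(attributes) if attributes is not None else list(clinical.data.columns)
    tasks = []
    for name in attrs:
        kind = clinical.types[name]
        col = clinical.attribute(name)
        if name in one_vs_rest:
            for level in sorted(col.dropna().astype(str).unique()):
                ind = (col.astype(str) == level).where(col.notna())
                if int(ind.sum()) < min_level_size:
                    log.info("skipping %s=%s (n=%d < %d)", name, level,
                             int(ind.sum()), min_level_size)
                    continue
                ind = ind.map({True: level, False: f"not_{level}"})
                ind.name = f"{name}:{level}"
                tasks.append((ind, "categorical", name))
        else:
            tasks.append((col, kind, name))
    for tissue, mod_profiles in profiles.items():
        for module, prof in mod_profiles.items():
            for attribute, kind, base in tasks:
                seed = derive_seed(master_seed, "assoc", tissue, module, attribute.name)
                try:
                    a = associate(prof.ranksum, attribute, kind, B=B, seed=seed,
                                  tissue=tissue, module=module)
                except ValueError as err:
                    log.info("skipping %s/%s vs %s: %s", tissue, module, attribute.name, err)
                    continue
                rows.append({**a.__dict__, "family": (families or {}).get(base, base)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = fdr_adjust(df["p_emp"].to_numpy(), df["family"].to_numpy())
    return df
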