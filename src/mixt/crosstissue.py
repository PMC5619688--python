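"""Cross-tissue module relationships: gene overlap and the MIxT statistic.

Two complementary notions of a tumor↔blood module relationship:

* **Gene-composition overlap** — one-sided hypergeometric enrichment of the
  shared gene count against the cohort's shared gene universe, BH-adjusted
  over all module pairs, significant at fdr < 0.01.  Modules that overlap
  this way are "mirrored" across tissues.

* **MIxT statistic** — Pearson correlation between the two modules'
  ranksum vectors over matched patients, so two modules interact when they
  order the patients similarly even with no genes in common.  Significance
  comes from permuting the tumor↔blood patient matching within the tested
  stratum (two-sided on |r|, add-one smoothing); subtype-specific scans
  (ssMIxT) repeat the test inside every subtype of every labeling scheme,
  skipping strata with fewer than ``min_stratum`` patients, and call
  interactions at a fixed alpha (0.005) without cross-stratum correction.
  An alternative caller places each observed r in the background
  distribution of all module-pair correlations within the stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import derive_seed, log
from .clinical import fdr_adjust


# ---------------------------------------------------------------------------
# gene-composition overlap
# ---------------------------------------------------------------------------

def module_overlap(modules_t, modules_b, universe,
                   fdr_threshold: float = 0.01) -> pd.DataFrame:
    """Hypergeometric enrichment of shared genes for every module pair.

    Both module sets are restricted to the shared ``universe`` (grey
    excluded); p is the one-sided upper tail (enrichment), BH-adjusted over
    all pairs.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    n_universe = len(universe)
    mods_t = {m: set(g) & universe for m, g in modules_t.modules().items()}
    mods_b = {m: set(g) & universe for m, g in modules_b.modules().items()}
    rows = []
    for mt, gt in mods_t.items():
        for mb, gb in mods_b.items():
            n_a, n_b = len(gt), len(gb)
            n_overlap = len(gt & gb)
            p = float(hypergeom.sf(n_overlap - 1, n_universe, n_a, n_b))
            rows.append({
                "tumor_module": mt, "blood_module": mb,
                "n_a": n_a, "n_b": n_b, "n_overlap": n_overlap,
                "n_universe": n_universe, "p": min(p, 1.0),
            })
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = fdr_adjust(df["p"].to_numpy(), np.zeros(len(df)))
        df["significant"] = df["fdr"] < fdr_threshold
    return df


# ---------------------------------------------------------------------------
# MIxT statistic
# ---------------------------------------------------------------------------

def mixt_statistic(rs_t: pd.Series, rs_b: pd.Series, stratum_samples=None,
                   B: int = 10_000, seed: int = 0) -> tuple:
    """(r, empirical two-sided p, direction) for one tumor/blood module pair.

    r is the Pearson correlation of the two ranksum vectors over the stratum
    patients; the null permutes the patient matching within the stratum for
    one tissue, which preserves each tissue's marginal ranksum distribution
    while breaking the tumor↔blood link.
    """
    if stratum_samples is None:
        stratum_samples = rs_t.index
    stratum_samples = pd.Index(stratum_samples)
    x = rs_t.loc[stratum_samples].to_numpy(dtype=float)
    y = rs_b.loc[stratum_samples].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"stratum too small for correlation (n={n})")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant ranksum on stratum")
    xs = (x - x.mean()) / x.std()
    ys = (y - y.mean()) / y.std()
    r = float(xs @ ys) / n
    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((B, n)), axis=1)
    r_perm = (ys[perms] @ xs) / n
    p = (1.0 + np.count_nonzero(np.abs(r_perm) >= abs(r) - 1e-12)) / (1.0 + B)
    direction = "positive" if r >= 0 else "negative"
    return r, float(p), direction


def _strata(clinical, schemes, patients, min_stratum: int):
    """Yield (scheme, stratum, samples) including the unstratified cohort."""
    yield "all", "all", pd.Index(patients), None
    for scheme in schemes:
        col = clinical.attribute(scheme).reindex(patients)
        for level in sorted(col.dropna().astype(str).unique()):
            members = col.index[col.astype(str) == level]
            if len(members) < min_stratum:
                yield scheme, level, members, (
                    f"stratum {scheme}={level} skipped (n={len(members)} < {min_stratum})")
            else:
                yield scheme, level, members, None


def run_ssmixt(profiles_t: dict, profiles_b: dict, clinical, schemes,
               B: int = 10_000, master_seed: int = 0, alpha: float = 0.005,
               min_stratum: int = 11) -> tuple:
    """Subtype-stratified MIxT scan over all tumor×blood module pairs.

    Tests stratum "all" plus every subtype level of every scheme with
    n >= min_stratum; returns (interaction table, skip log).  Per-test
    seeds are derived from the master seed and the test identifiers.
    """
    schemes = list(schemes)
    if not schemes:
        raise ValueError("no subtyping scheme columns given")
    patients = next(iter(profiles_t.values())).ranksum.index
    rows, skipped = [], []
    for scheme, stratum, members, skip in _strata(clinical, schemes, patients, min_stratum):
        if skip is not None:
            log.info(skip)
            skipped.append(skip)
            continue
        for mt, pt in profiles_t.items():
            for mb, pb in profiles_b.items():
                seed = derive_seed(master_seed, "mixt", scheme, stratum, mt, mb)
                try:
                    r, p, direction = mixt_statistic(
                        pt.ranksum, pb.ranksum, members, B=B, seed=seed)
                except ValueError as err:
                    msg = f"pair {mt}/{mb} in {scheme}={stratum} skipped: {err}"
                    log.info(msg)
                    skipped.append(msg)
                    continue
                rows.append({
                    "scheme": scheme, "stratum": stratum,
                    "tumor_module": mt, "blood_module": mb,
                    "n": len(members), "r": r, "p_emp": p,
                    "direction": direction, "significant": p < alpha,
                    "B": B, "seed": seed,
                })
    return pd.DataFrame(rows), skipped


def background_distribution(profiles_t: dict, profiles_b: dict,
                            stratum_samples=None,
                            quantiles: tuple = (0.025, 0.975)) -> dict:
    """All-pairs background of ranksum correlations within a stratum.

    The alternative caller: every module pair's observed r, with empirical
    lower/upper bounds at the given quantiles; a pair is an outlying
    interaction when its r falls outside the bounds.  Degenerate (zero
    spread) backgrounds are flagged rather than called.
    """
    if len(profiles_t) < 2 or len(profiles_b) < 2:
        raise ValueError("need >=2 modules per tissue for a background")
    rows = []
    for mt, pt in profiles_t.items():
        for mb, pb in profiles_b.items():
            samples = (pd.Index(stratum_samples) if stratum_samples is not None
                       else pt.ranksum.index)
            x = pt.ranksum.loc[samples].to_numpy(dtype=float)
            y = pb.ranksum.loc[samples].to_numpy(dtype=float)
            r = float(np.corrcoef(x, y)[0, 1])
            rows.append({"tumor_module": mt, "blood_module": mb, "r": r})
    df = pd.DataFrame(rows)
    lo, hi = np.quantile(df["r"], quantiles)
    degenerate = bool(np.isclose(lo, hi))
    if degenerate:
        log.warning("degenerate background: all module-pair correlations identical")
        df["outside_background"] = False
    else:
        df["outside_background"] = (df["r"] < lo) | (df["r"] > hi)
    return {"pairs": df, "lower": float(lo), "upper": float(hi),
            "degenerate": degenerate}
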