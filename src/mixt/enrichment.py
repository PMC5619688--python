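"""Gene-set enrichment of modules by minimum-likelihood hypergeometric tests.

For a module (or its ranksum-positive "up" / ranksum-negative "dn" gene
subsets) and a gene set, the p-value sums the hypergeometric probabilities
of every possible overlap count whose likelihood does not exceed that of
the observed overlap.  When the observed overlap exceeds its expectation
this reduces to the familiar one-sided upper tail (one-sided Fisher exact
test); at the modal overlap it is exactly 1.  BH FDR is applied per
collection × subset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import log
from .clinical import fdr_adjust

SUBSETS = ("all", "up", "dn")


def minimum_likelihood_pval(n_universe: int, n_set: int, n_subset: int,
                            n_overlap: int) -> float:
    """Sum of hypergeometric pmf over outcomes no more likely than observed."""
    if not (0 <= n_set <= n_universe and 0 <= n_subset <= n_universe):
        raise ValueError("set/subset sizes must lie within the universe")
    lo = max(0, n_set + n_subset - n_universe)
    hi = min(n_set, n_subset)
    if not lo <= n_overlap <= hi:
        raise ValueError(f"impossible overlap {n_overlap} for "
                         f"(N={n_universe}, K={n_set}, n={n_subset})")
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_universe, n_set, n_subset)
    p_obs = pmf[n_overlap - lo]
    # relative tolerance so float noise cannot drop ties with the observed pmf
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(max(p, np.nextafter(0, 1)), 1.0)


def enrich(genes, collection, universe) -> pd.DataFrame:
    """Minimum-likelihood hypergeometric enrichment of a gene subset.

    ``genes`` must lie within ``universe``; each collection set is
    intersected with the universe first (sets with no universe gene are
    dropped with a warning).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    genes = set(genes)
    outside = genes - universe
    if outside:
        raise ValueError(f"subset genes outside the universe: {sorted(outside)[:5]}")
    rows = []
    for name, members in collection:
        in_univ = set(members) & universe
        if not in_univ:
            log.warning("gene set %s has no genes in the universe; dropped", name)
            continue
        n_overlap = len(genes & in_univ)
        rows.append({
            "set": name,
            "n_overlap": n_overlap,
            "n_set": len(in_univ),
            "n_subset": len(genes),
            "n_universe": len(universe),
            "p": minimum_likelihood_pval(len(universe), len(in_univ),
                                         len(genes), n_overlap),
        })
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = fdr_adjust(df["p"].to_numpy(), np.zeros(len(df)))
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df


def enrich_module(profile, collection, universe,
                  collection_name: str = "collection") -> pd.DataFrame:
    """Enrichment of a module's all/up/dn gene subsets, FDR per subset.

    "up"/"dn" are the member genes positively/negatively correlated with the
    patient ranksum; an empty subset is skipped with a log entry.
    """
    orientation = profile.gene_orientation
    subsets = {
        "all": list(orientation.index),
        "up": list(orientation.index[orientation > 0]),
        "dn": list(orientation.index[orientation < 0]),
    }
    frames = []
    for subset_name, genes in subsets.items():
        if not genes:
            log.info("module %s: subset %r empty, skipped", profile.module, subset_name)
            continue
        df = enrich([g for g in genes if g in universe], collection, universe)
        df.insert(0, "subset", subset_name)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "module", profile.module)
    out.insert(0, "tissue", profile.tissue)
    out.insert(0, "collection", collection_name)
    return out
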