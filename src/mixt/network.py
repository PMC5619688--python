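"""Unsigned weighted co-expression network and module detection.

Per tissue: Pearson correlation between all gene pairs, soft-thresholded
unsigned adjacency a_ij = |cor(i,j)|^beta (beta=6 by default), topological
overlap (TOM), average-linkage clustering of 1-TOM, and branch cutting with
a dynamic-hybrid-style procedure:

  1. candidate branches from an adaptive cut of the dendrogram (the cut
     height is placed in the widest gap of the upper merge-height
     distribution; deep_split selects progressively lower candidate gaps);
  2. branches smaller than min_module_size become "grey" (unassigned);
  3. a PAM-like stage reassigns grey genes to the closest module when their
     mean TOM-dissimilarity to it falls within that module's internal spread;
  4. modules whose eigengenes (first PC of standardized member expression,
     sign-oriented) correlate above merge_threshold are merged iteratively;
  5. final modules are renamed by decreasing size with the conventional
     color palette; "grey" is reserved for unassigned genes and excluded
     from all downstream statistics.

Similarity/adjacency/TOM matrices are square DataFrames indexed by gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from ._util import log
from .data_io import ExpressionMatrix

GREY = "grey"

#: size-ordered module name palette (cosmetic, echoes the conventional scheme)
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "skyblue3", "plum", "orangered", "mediumpurple",
]


def _module_name(i: int) -> str:
    return MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}"


@dataclass
class ModuleSet:
    """Gene → module assignment for one tissue.

    ``assignment`` maps every network gene to a module label; ``"grey"``
    marks unassigned genes and is excluded from :meth:`modules`.
    """

    tissue: str
    assignment: pd.Series
    params: dict = field(default_factory=dict)

    def modules(self) -> dict:
        """Named modules (label → list of genes), grey excluded, size-ordered."""
        out = {}
        for label, genes in self.assignment.groupby(self.assignment):
            if label != GREY:
                out[label] = list(genes.index)
        return dict(sorted(out.items(), key=lambda kv: -len(kv[1])))

    @property
    def labels(self) -> list:
        return list(self.modules().keys())

    def __len__(self):
        return len(self.modules())


# ---------------------------------------------------------------------------
# similarity / adjacency / TOM
# ---------------------------------------------------------------------------

def correlation_matrix(expr: ExpressionMatrix, samples=None,
                       method: str = "pearson") -> pd.DataFrame:
    """Gene×gene correlation across the given samples (default: patients).

    Pearson by default, configurable to Spearman.  Zero-variance genes are
    rejected by name — a constant gene has no defined correlation.
    """
    if samples is None:
        samples = expr.patient_samples
    samples = pd.Index(samples)
    if len(samples) < 3:
        raise ValueError(f"need >=3 samples for correlations, got {len(samples)}")
    x = expr.values[samples].to_numpy(dtype=float)
    if method == "spearman":
        from scipy.stats import rankdata
        x = rankdata(x, axis=1)
    spread = np.ptp(x, axis=1)
    if (spread == 0).any():
        gene = expr.gene_ids[np.flatnonzero(spread == 0)[0]]
        raise ValueError(f"zero-variance gene on the sample subset: {gene!r}")
    c = np.corrcoef(x)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=expr.gene_ids, columns=expr.gene_ids)


def adjacency(sim: pd.DataFrame, beta: float = 6.0) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency a_ij = |s_ij|^beta."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    a = np.abs(sim.to_numpy(dtype=float)) ** beta
    return pd.DataFrame(a, index=sim.index, columns=sim.columns)


def topological_overlap(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j
    with connectivity k_i = sum_{u != i} a_iu (diagonal excluded), TOM_ii = 1.
    Measures shared network neighborhood on top of direct adjacency.
    """
    a = adj.to_numpy(dtype=float).copy()
    if not np.isfinite(a).all():
        raise ValueError("adjacency contains non-finite values")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


# ---------------------------------------------------------------------------
# dendrogram cutting
# ---------------------------------------------------------------------------

def _cut_height_from_gaps(heights: np.ndarray, deep_split: int) -> float:
    """Place the cut in a wide gap of the upper merge-height distribution.

    Merge heights of a structured TOM dendrogram separate into a low band
    (within-branch merges) and a high band (between-branch and background
    joins); the widest gap between consecutive sorted heights above the
    median marks the boundary.  Higher deep_split values select the next
    lower qualifying gap, producing finer branches.
    """
    hs = np.sort(heights)
    lo = np.median(hs)
    idx = np.flatnonzero(hs[:-1] >= lo)
    if len(idx) == 0:
        return float(hs[-1]) - 1e-12
    gaps = hs[idx + 1] - hs[idx]
    order = idx[np.argsort(gaps)[::-1]]  # gap positions, widest first
    # keep only gaps at least 20% as wide as the widest, then sort by height
    widest = gaps.max()
    cand = sorted(i for i in order if hs[i + 1] - hs[i] >= 0.2 * widest)
    cand = cand[::-1]  # highest cut first
    pick = min(max(int(deep_split), 0) // 2, len(cand) - 1)
    i = cand[pick]
    return float(hs[i] + 0.5 * (hs[i + 1] - hs[i]))


def _branch_labels(linkage: np.ndarray, n: int, min_module_size: int,
                   deep_split: int) -> np.ndarray:
    """Integer candidate-branch labels; 0 = unassigned."""
    heights = linkage[:, 2]
    cut = _cut_height_from_gaps(heights, deep_split)
    flat = sch.fcluster(linkage, t=cut, criterion="distance")
    labels = np.zeros(n, dtype=int)
    nxt = 1
    for cl in np.unique(flat):
        members = np.flatnonzero(flat == cl)
        if len(members) >= min_module_size:
            labels[members] = nxt
            nxt += 1
    return labels


def _reassign_grey(labels: np.ndarray, dissim: np.ndarray,
                   min_module_size: int) -> np.ndarray:
    """PAM-like stage: pull unassigned genes into their closest module.

    A grey gene joins the module with the smallest mean dissimilarity to its
    members, but only if that distance lies within the module's own internal
    spread (mean + 1 sd of within-module dissimilarities); genes that are
    far from every module stay grey.
    """
    labels = labels.copy()
    mods = [m for m in np.unique(labels) if m != 0]
    if not mods:
        return labels
    stats = {}
    for m in mods:
        members = np.flatnonzero(labels == m)
        sub = dissim[np.ix_(members, members)]
        iu = np.triu_indices(len(members), k=1)
        within = sub[iu]
        stats[m] = (members, within.mean(), within.std())
    for g in np.flatnonzero(labels == 0):
        mean_d = {m: dissim[g, stats[m][0]].mean() for m in mods}
        best = min(mods, key=lambda m: (mean_d[m], m))
        _, mu, sd = stats[best]
        if mean_d[best] <= mu + sd:
            labels[g] = best
    return labels


# ---------------------------------------------------------------------------
# eigengenes and merging
# ---------------------------------------------------------------------------

def module_eigengene(expr_values: np.ndarray) -> np.ndarray:
    """First principal component over samples of gene-standardized expression.

    Sign-oriented so the mean gene–eigengene correlation is positive (PCA
    sign ambiguity removed deterministically).
    """
    x = np.asarray(expr_values, dtype=float)
    z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    # first right singular vector = PC scores over samples
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    cors = (z @ (e - e.mean())) / (
        np.linalg.norm(z, axis=1) * np.linalg.norm(e - e.mean()) + 1e-300
    )
    if cors.mean() < 0:
        e = -e
    return e


def merge_modules(assignment: pd.Series, expr: ExpressionMatrix, samples,
                  merge_threshold: float = 0.75) -> pd.Series:
    """Iteratively merge module pairs whose eigengenes correlate above threshold.

    The most-correlated pair is merged first and eigengenes recomputed, so
    rerunning on the output is a no-op (idempotent).
    """
    samples = pd.Index(samples)
    assignment = assignment.copy()
    x = expr.values[samples]

    def eigengenes(assn):
        return {
            m: module_eigengene(x.loc[genes].to_numpy())
            for m, genes in assn.groupby(assn).groups.items()
            if m != GREY
        }

    eg = eigengenes(assignment)
    while len(eg) > 1:
        mods = sorted(eg)
        emat = np.array([eg[m] for m in mods])
        c = np.corrcoef(emat)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= merge_threshold:
            break
        keep, drop = sorted((mods[i], mods[j]))
        assignment[assignment == drop] = keep
        eg = eigengenes(assignment)
    return assignment


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

def detect_modules(tom: pd.DataFrame, expr: ExpressionMatrix,
                   min_module_size: int = 30, deep_split: int = 2,
                   merge_threshold: float = 0.75, pam_stage: bool = True,
                   samples=None, beta: float = 6.0, seed: int = 0) -> ModuleSet:
    """Detect co-expression modules from a TOM via average-linkage clustering.

    Branches come from cutting the 1-TOM dendrogram (see module docstring);
    candidate modules below ``min_module_size`` and genes distant from every
    module are labeled grey.  Similar modules are merged on eigengene
    correlation, then relabeled by decreasing size.
    """
    genes = tom.index
    n = len(genes)
    if n < 2 * min_module_size:
        raise ValueError(f"too few genes ({n}) for min_module_size={min_module_size}")
    t = tom.to_numpy(dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("TOM contains non-finite values")
    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    dissim = np.maximum(dissim, 0.0)
    linkage = sch.linkage(squareform(dissim, checks=False), method="average")

    labels = _branch_labels(linkage, n, min_module_size, deep_split)
    if pam_stage:
        labels = _reassign_grey(labels, dissim, min_module_size)

    if samples is None:
        samples = expr.patient_samples
    assignment = pd.Series(
        [f"m{l:04d}" if l else GREY for l in labels],
        index=pd.Index(genes, name="gene"),
    )
    if labels.max() >= 1:
        assignment = merge_modules(assignment, expr, samples, merge_threshold)

    # drop modules that fell below min size, then relabel by decreasing size
    sizes = assignment[assignment != GREY].value_counts()
    for m in sizes.index[sizes < min_module_size]:
        assignment[assignment == m] = GREY
    sizes = assignment[assignment != GREY].value_counts()
    order = sorted(sizes.index, key=lambda m: (-sizes[m], m))
    rename = {m: _module_name(i) for i, m in enumerate(order)}
    rename[GREY] = GREY
    assignment = assignment.map(rename)

    log.info("detected %d modules (+%d grey genes) in %s",
             len(order), int((assignment == GREY).sum()), expr.tissue)
    return ModuleSet(
        tissue=expr.tissue,
        assignment=assignment,
        params={
            "beta": beta, "min_module_size": min_module_size,
            "deep_split": deep_split, "merge_threshold": merge_threshold,
            "pam_stage": pam_stage, "seed": seed,
        },
    )


def build_network_modules(expr: ExpressionMatrix, beta: float = 6.0,
                          min_module_size: int = 30, deep_split: int = 2,
                          merge_threshold: float = 0.75, samples=None,
                          method: str = "pearson", seed: int = 0):
    """Convenience: correlation → adjacency → TOM → modules for one tissue.

    Networks are built on matched patients only; controls never enter the
    similarity computation.
    """
    sim = correlation_matrix(expr, samples=samples, method=method)
    adj = adjacency(sim, beta=beta)
    tom = topological_overlap(adj)
    mods = detect_modules(
        tom, expr, min_module_size=min_module_size, deep_split=deep_split,
        merge_threshold=merge_threshold, samples=samples, beta=beta, seed=seed,
    )
    return tom, mods


# ---------------------------------------------------------------------------
# edge export
# ---------------------------------------------------------------------------

def export_edges(tom: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Undirected edges with TOM strictly above threshold, isolated nodes removed.

    Returns a TSV-ready frame (gene_a, gene_b, topological_overlap); the set
    of genes appearing in it is the node set after removing isolated nodes.
    """
    t = tom.to_numpy(dtype=float)
    iu = np.triu_indices(len(t), k=1)
    mask = t[iu] > threshold
    ia, ja = iu[0][mask], iu[1][mask]
    edges = pd.DataFrame({
        "gene_a": tom.index[ia],
        "gene_b": tom.index[ja],
        "topological_overlap": t[iu][mask],
    })
    n_nodes = len(set(edges["gene_a"]) | set(edges["gene_b"]))
    log.info("edge export at TOM > %g: %d edges, %d nodes", threshold, len(edges), n_nodes)
    return edges
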