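"""Signed-hybrid weighted co-expression network construction and module statistics.

Pipeline: pick the most variable genes, raise positive Pearson correlations
to a soft power beta (negative correlations are zeroed — the signed hybrid
convention), convert to topological overlap (TOM), cluster 1 - TOM with
average linkage, cut statically, merge modules with correlated eigengenes,
and relate the result to external condition variables via module-trait
correlations, gene significance (GS) and module membership (MM).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

#: Module labels in assignment order (largest module first); "grey" is
#: reserved for unassigned genes.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class CoexpressionNetwork:
    genes: list[str]
    correlation: np.ndarray
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray
    connectivity: pd.Series


@dataclass
class ModulePartition:
    labels: pd.Series                    # gene -> color label, "grey" unassigned
    eigengenes: pd.DataFrame             # samples x modules ("ME<color>")
    merge_history: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != "grey"]


def select_top_variable(logexpr: pd.DataFrame, n: int = 2500) -> pd.DataFrame:
    """The n genes with the highest log-expression variance (ties by gene ID)."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if n > len(logexpr):
        raise ValueError(f"requested {n} genes from a matrix with {len(logexpr)}")
    variances = logexpr.var(axis=1, ddof=1)
    order = sorted(logexpr.index, key=lambda g: (-variances[g], g))
    chosen = sorted(order[:n], key=list(logexpr.index).index)
    return logexpr.loc[chosen]


def _pearson_matrix(logexpr: pd.DataFrame) -> np.ndarray:
    vals = logexpr.to_numpy(dtype=float)
    sd = vals.std(axis=1)
    if (sd == 0).any():
        bad = logexpr.index[sd == 0].tolist()
        raise ValueError(f"zero-variance gene(s): {bad[:5]}")
    return np.corrcoef(vals)


def signed_hybrid_adjacency(logexpr: pd.DataFrame, beta: float = 8.0) -> np.ndarray:
    """a_ij = max(cor_ij, 0)**beta off-diagonal; diagonal 1."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if logexpr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    cor = _pearson_matrix(logexpr)
    adj = np.clip(cor, 0.0, 1.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return adj


def connectivity(adjacency: np.ndarray) -> np.ndarray:
    """Whole-network connectivity k_i (self excluded)."""
    return adjacency.sum(axis=1) - np.diag(adjacency)


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> tuple[float, float, float]:
    """Scale-free topology fit of the connectivity distribution.

    Connectivity is discretized into equal-width bins; the proportion of
    nodes per occupied bin, log10 p(k), is regressed on the log10 bin mean
    of k.  Returns (signed R^2, slope, mean k), with signed R^2 =
    R^2 * sign(-slope) so topologies with the canonical decreasing degree
    distribution score positively.
    """
    if adjacency.shape[0] < 20:
        raise ValueError("need at least 20 genes for a meaningful fit")
    k = connectivity(adjacency)
    k = np.maximum(k, 0.0)
    if np.allclose(k, k[0]):
        raise ValueError("all connectivities equal: degenerate degree distribution")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    n = len(k)
    for b in range(n_bins):
        members = k[idx == b]
        if len(members) == 0 or members.mean() <= 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(len(members) / n))
    if len(xs) < 3:
        raise ValueError("degenerate binning: fewer than 3 occupied bins")
    slope, _, r, _, _ = stats.linregress(xs, ys)
    if not np.isfinite(r):
        raise ValueError("degenerate binning: constant bin occupancy")
    signed_r2 = r ** 2 * (1.0 if slope < 0 else -1.0)
    return float(signed_r2), float(slope), float(k.mean())


def pick_soft_threshold(
    logexpr: pd.DataFrame,
    candidate_betas: tuple[int, ...] = tuple(range(1, 21)),
    r2_cut: float = 0.8,
) -> tuple[int, pd.DataFrame]:
    """Smallest beta whose signed scale-free R^2 reaches r2_cut.

    Falls back to the beta of maximal signed R^2 when none reaches the cut.
    Also returns the full fit table (beta, signed R^2, slope, mean k).
    """
    if not candidate_betas:
        raise ValueError("no candidate betas")
    rows = []
    for b in candidate_betas:
        adj = signed_hybrid_adjacency(logexpr, beta=b)
        try:
            r2, slope, meank = scale_free_fit(adj)
        except ValueError:
            r2, slope, meank = -1.0, 0.0, float(connectivity(adj).mean())
        if not np.isfinite(r2):
            r2 = -1.0
        rows.append({"beta": b, "signed_r2": r2, "slope": slope, "mean_k": meank})
    table = pd.DataFrame(rows)
    passing = table[table["signed_r2"] >= r2_cut]
    if len(passing):
        beta = int(passing["beta"].iloc[0])
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "beta"])
    return beta, table


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), diagonal 1.

    l_ij sums a_iu * a_uj over shared neighbours u distinct from i and j.
    """
    a = adjacency.copy().astype(float)
    np.fill_diagonal(a, 0.0)
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    tom: np.ndarray,
    genes: list[str],
    min_module_size: int = 30,
    cut_height: float = 0.99,
) -> ModulePartition:
    """Average-linkage clustering of 1 - TOM with a static branch cut.

    Clusters smaller than min_module_size become "grey"; surviving clusters
    get color labels in decreasing size order.  Eigengenes are filled in by
    :func:`module_eigengenes`.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2.0, 0.0, None)
    z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    raw = hierarchy.fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    by_size = sorted(sizes.index, key=lambda cid: (-int(sizes[cid]), int(cid)))
    labels = pd.Series("grey", index=pd.Index(genes, name="gene"), dtype=object)
    color_iter = iter(MODULE_COLORS)
    used = 0
    for cluster_id in by_size:
        if sizes[cluster_id] < min_module_size:
            continue
        try:
            color = next(color_iter)
        except StopIteration:
            used += 1
            color = f"module{used + len(MODULE_COLORS)}"
        labels[np.asarray(raw) == cluster_id] = color
    return ModulePartition(labels=labels, eigengenes=pd.DataFrame())


def module_eigengenes(
    logexpr: pd.DataFrame, labels: pd.Series, include_grey: bool = False
) -> pd.DataFrame:
    """First principal component of each module across samples (unit norm).

    Genes are z-scored first; the eigengene sign is aligned so that its
    correlation with the module's mean expression profile is non-negative.
    Zero-variance genes are dropped from the SVD with a logged warning.
    """
    samples = logexpr.columns
    out = {}
    modules = [m for m in pd.unique(labels) if include_grey or m != "grey"]
    for m in modules:
        sub = logexpr.loc[labels[labels == m].index].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            log.warning("module %s: dropping %d zero-variance gene(s) from SVD", m, int((sd == 0).sum()))
            sub = sub[sd > 0]
            sd = sd[sd > 0]
        if len(sub) < 2:
            raise ValueError(f"module {m!r} has fewer than 2 usable genes")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = sub.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        out[f"ME{m}"] = me / np.linalg.norm(me)
    return pd.DataFrame(out, index=samples)


def merge_modules(
    partition: ModulePartition,
    logexpr: pd.DataFrame,
    merge_height: float = 0.25,
) -> ModulePartition:
    """Merge modules whose eigengenes correlate at >= 1 - merge_height.

    Single linkage on 1 - cor(ME): chains of pairwise-similar modules
    collapse into one.  Eigengenes are recomputed; the surviving label of a
    merged group is its largest member's.
    """
    labels = partition.labels.copy()
    modules = [m for m in labels.unique() if m != "grey"]
    if len(modules) < 2:
        mes = module_eigengenes(logexpr, labels) if modules else pd.DataFrame()
        return ModulePartition(labels=labels, eigengenes=mes,
                               merge_history=list(partition.merge_history))
    mes = module_eigengenes(logexpr, labels)
    cor = np.corrcoef(mes.to_numpy().T)
    diss = np.clip(1.0 - cor, 0.0, None)
    np.fill_diagonal(diss, 0.0)
    z = hierarchy.linkage(squareform(diss, checks=False), method="single")
    groups = hierarchy.fcluster(z, t=merge_height, criterion="distance")

    me_names = [c[2:] for c in mes.columns]  # strip "ME"
    history = list(partition.merge_history)
    sizes = labels.value_counts()
    for gid in np.unique(groups):
        members = [me_names[i] for i in np.flatnonzero(groups == gid)]
        if len(members) < 2:
            continue
        keep = max(members, key=lambda m: (sizes.get(m, 0), m))
        for m in members:
            if m != keep:
                labels[labels == m] = keep
        history.append(tuple(sorted(members)) + (f"->{keep}",))
    new_mes = module_eigengenes(logexpr, labels)
    return ModulePartition(labels=labels, eigengenes=new_mes, merge_history=history)


def _cor_with_p(x: np.ndarray, y: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation of rows of x with rows of y, plus Student-t p-values."""
    xz = (x - x.mean(axis=1, keepdims=True))
    yz = (y - y.mean(axis=1, keepdims=True))
    xn = np.linalg.norm(xz, axis=1, keepdims=True)
    yn = np.linalg.norm(yz, axis=1, keepdims=True)
    if (xn == 0).any() or (yn == 0).any():
        raise ValueError("constant vector in correlation")
    r = np.clip((xz / xn) @ (yz / yn).T, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return r, p


def module_trait_correlation(
    eigengenes: pd.DataFrame, conditions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module x condition Pearson correlations and asymptotic p-values."""
    n = len(eigengenes)
    cvals = conditions.to_numpy(dtype=float).T
    if any(np.allclose(row, row[0]) for row in cvals):
        raise ValueError("constant condition vector")
    r, p = _cor_with_p(eigengenes.to_numpy().T, cvals, n)
    rdf = pd.DataFrame(r, index=eigengenes.columns, columns=conditions.columns)
    pdf = pd.DataFrame(p, index=eigengenes.columns, columns=conditions.columns)
    return rdf, pdf


def gene_significance(
    logexpr: pd.DataFrame, condition: pd.Series
) -> pd.DataFrame:
    """Per-gene correlation with a condition variable (GS) and its p-value."""
    c = condition.to_numpy(dtype=float)[None, :]
    if np.allclose(c, c[0, 0]):
        raise ValueError("constant condition vector")
    r, p = _cor_with_p(logexpr.to_numpy(dtype=float), c, logexpr.shape[1])
    return pd.DataFrame({"gs": r[:, 0], "p": p[:, 0]}, index=logexpr.index)


def module_membership(
    logexpr: pd.DataFrame, eigengenes: pd.DataFrame
) -> pd.DataFrame:
    """Gene x module correlations with the module eigengenes (MM)."""
    r, _ = _cor_with_p(
        logexpr.to_numpy(dtype=float), eigengenes.to_numpy().T, logexpr.shape[1]
    )
    return pd.DataFrame(r, index=logexpr.index, columns=eigengenes.columns)


def build_network(
    logexpr: pd.DataFrame, beta: float = 8.0
) -> CoexpressionNetwork:
    """Correlation -> signed-hybrid adjacency -> TOM in one call."""
    cor = _pearson_matrix(logexpr)
    adj = np.clip(cor, 0.0, 1.0) ** beta
    np.fill_diagonal(adj, 1.0)
    tom = topological_overlap(adj)
    k = connectivity(adj)
    return CoexpressionNetwork(
        genes=list(logexpr.index),
        correlation=cor,
        beta=beta,
        adjacency=adj,
        tom=tom,
        connectivity=pd.Series(k, index=logexpr.index, name="k"),
    )
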