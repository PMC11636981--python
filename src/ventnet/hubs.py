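"""Thresholded network graph, maximal-clique-centrality hubs and first-neighbour alliances.

The weighted network (TOM by default) is turned into a simple graph by an
edge-weight filter, an optional per-node top-k strongest-edge filter, and an
iterative strict degree filter.  Hubs are scored with maximal clique
centrality (MCC): the sum of (|C| - 1)! over all maximal cliques C containing
the node, with the convention that a node whose open neighbourhood is
edgeless scores its degree.  "Alliances" are the patterns of sharing between
the first-neighbour sets of designated pathway seed gene sets.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ThresholdedGraph:
    graph: nx.Graph
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": min(u, v), "target": max(u, v), "weight": d["weight"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "weight"])
        return df.sort_values(["source", "target"]).reset_index(drop=True)


def threshold_network(
    genes: list[str],
    weights: np.ndarray,
    weight_source: str = "tom",
    min_weight: float = 0.05,
    min_degree: int = 2,
    top_k_per_node: int | None = None,
) -> ThresholdedGraph:
    """Edge-weight > min_weight, optional per-node top-k, then iterative degree > min_degree.

    The top-k filter keeps an edge if it ranks among the k strongest
    surviving edges of either endpoint.  The degree filter removes nodes
    with degree <= min_degree repeatedly until stable (strict, as printed).
    An empty result is returned with a warning, never raised.
    """
    w = np.asarray(weights, dtype=float)
    n = len(genes)
    if w.shape != (n, n):
        raise ValueError("weight matrix shape must match gene list")

    g = nx.Graph()
    g.add_nodes_from(genes)
    iu, ju = np.triu_indices(n, k=1)
    keep = w[iu, ju] > min_weight
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(genes[i], genes[j], weight=float(w[i, j]))

    if top_k_per_node is not None:
        keep_edges: set[tuple[str, str]] = set()
        for node in g.nodes:
            ranked = sorted(
                g.edges(node, data="weight"),
                key=lambda e: (-e[2], e[0], e[1]),
            )[:top_k_per_node]
            for u, v, _ in ranked:
                keep_edges.add((min(u, v), max(u, v)))
        drop = [
            (u, v) for u, v in g.edges
            if (min(u, v), max(u, v)) not in keep_edges
        ]
        g.remove_edges_from(drop)

    while True:
        low = [v for v, d in g.degree if d <= min_degree]
        if not low:
            break
        g.remove_nodes_from(low)

    if g.number_of_nodes() == 0:
        warnings.warn("thresholding removed every node", stacklevel=2)
    return ThresholdedGraph(
        graph=g,
        provenance={
            "weight_source": weight_source,
            "min_weight": min_weight,
            "min_degree": min_degree,
            "top_k_per_node": top_k_per_node,
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
        },
    )


def mcc_scores(graph: nx.Graph | ThresholdedGraph) -> pd.Series:
    """Maximal clique centrality per node.

    MCC(v) = sum over maximal cliques C containing v of (|C| - 1)!,
    except that a node whose open neighbourhood contains no edges scores
    its degree (so leaves score 1 and isolated nodes 0).  Maximal cliques
    are enumerated exactly (Bron-Kerbosch with pivoting).
    """
    g = graph.graph if isinstance(graph, ThresholdedGraph) else graph
    scores = {v: 0.0 for v in g.nodes}
    edgeless_nbhd = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        edgeless_nbhd[v] = not any(
            g.has_edge(a, b) for a, b in itertools.combinations(nbrs, 2)
        )
    for clique in nx.find_cliques(g):
        contribution = math.factorial(len(clique) - 1)
        for v in clique:
            if not edgeless_nbhd[v]:
                scores[v] += contribution
    for v in g.nodes:
        if edgeless_nbhd[v]:
            scores[v] = float(g.degree[v])
    return pd.Series(scores, name="mcc").sort_index()


def rank_hubs(
    scores: pd.Series, graph: nx.Graph | ThresholdedGraph, top_n: int | None = None
) -> pd.DataFrame:
    """Hubs by descending MCC; ties broken by degree, then gene ID."""
    g = graph.graph if isinstance(graph, ThresholdedGraph) else graph
    df = pd.DataFrame(
        {
            "gene": scores.index,
            "mcc": scores.values,
            "degree": [g.degree[v] if v in g else 0 for v in scores.index],
        }
    )
    df = df.sort_values(
        ["mcc", "degree", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    if top_n is not None:
        if top_n > len(df):
            warnings.warn(
                f"requested top {top_n} hubs from {len(df)} nodes; returning all",
                stacklevel=2,
            )
        df = df.head(top_n)
    return df


def first_neighbors(
    graph: nx.Graph | ThresholdedGraph, seed_set: set[str] | list[str]
) -> set[str]:
    """Union of direct neighbours of the seed genes, excluding the seeds."""
    g = graph.graph if isinstance(graph, ThresholdedGraph) else graph
    seeds = set(seed_set)
    missing = seeds - set(g.nodes)
    if missing:
        warnings.warn(
            f"{len(missing)} seed gene(s) absent from the graph: "
            f"{sorted(missing)[:5]}",
            stacklevel=2,
        )
    out: set[str] = set()
    for s in seeds & set(g.nodes):
        out.update(g.neighbors(s))
    return out - seeds


@dataclass
class AllianceResult:
    neighbor_sets: dict[str, set[str]]
    membership: pd.DataFrame                  # gene x set, binary
    intersections: pd.DataFrame               # one row per non-empty exclusive combination
    pairwise: pd.DataFrame                    # set_a, set_b, shared, jaccard
    category_counts: pd.DataFrame | None = None
    unknown_category_genes: int = 0


def alliance_matrix(
    neighbor_sets: dict[str, set[str]],
    category_map: dict[str, list[str]] | None = None,
) -> AllianceResult:
    """Intersection structure of named first-neighbour sets (UpSet-style).

    ``intersections`` lists, for every combination of sets that some gene
    belongs to exactly (exclusive intersections, as an UpSet plot shows
    them), the number of such genes.  ``pairwise`` reports plain shared
    counts and Jaccard indices.  ``category_counts`` (when a gene ->
    categories map is supplied) counts, per functional category, the
    neighbours shared with each named set; genes in the map that appear in
    no set are tallied, not an error.
    """
    names = sorted(neighbor_sets)
    all_genes = sorted(set().union(*neighbor_sets.values())) if names else []
    membership = pd.DataFrame(
        {name: [g in neighbor_sets[name] for g in all_genes] for name in names},
        index=pd.Index(all_genes, name="gene"),
        dtype=int,
    )

    combos: dict[tuple[str, ...], int] = {}
    for _, row in membership.iterrows():
        key = tuple(n for n in names if row[n])
        combos[key] = combos.get(key, 0) + 1
    inter_rows = [
        {"sets": "&".join(k), "degree": len(k), "count": v}
        for k, v in sorted(combos.items(), key=lambda kv: (-len(kv[0]), kv[0]))
    ]
    intersections = pd.DataFrame(inter_rows, columns=["sets", "degree", "count"])

    pair_rows = []
    for a, b in itertools.combinations(names, 2):
        sa, sb = neighbor_sets[a], neighbor_sets[b]
        inter, union = len(sa & sb), len(sa | sb)
        pair_rows.append(
            {
                "set_a": a,
                "set_b": b,
                "shared": inter,
                "jaccard": inter / union if union else 0.0,
            }
        )
    pairwise = pd.DataFrame(pair_rows, columns=["set_a", "set_b", "shared", "jaccard"])

    category_counts = None
    unknown = 0
    if category_map is not None:
        in_any = set(all_genes)
        unknown = sum(1 for g in category_map if g not in in_any)
        cat_rows = []
        cats = sorted({c for cl in category_map.values() for c in cl})
        for cat in cats:
            cat_genes = {g for g, cl in category_map.items() if cat in cl}
            row = {"category": cat}
            for name in names:
                row[name] = len(cat_genes & neighbor_sets[name])
            cat_rows.append(row)
        category_counts = pd.DataFrame(cat_rows, columns=["category", *names])

    return AllianceResult(
        neighbor_sets={k: set(v) for k, v in neighbor_sets.items()},
        membership=membership,
        intersections=intersections,
        pairwise=pairwise,
        category_counts=category_counts,
        unknown_category_genes=unknown,
    )
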