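"""Thresholded correlation graphs and Markov clustering (MCL).

Co-expression structure is read from a graph whose nodes are genes (or
promoters) and whose edges are correlations at or above a threshold
(gene atlas: Pearson r >= 0.8; sample graph: Spearman rho >= 0.82; the
promoter/CAGE preset: 0.75 after dropping promoters never exceeding 10
tags per million).  Clusters are extracted with a from-scratch Markov
clustering implementation: the column-stochastic transition matrix is
alternately expanded (squared) and inflated (entry-wise power, then
column renormalisation) until it converges to a set of attractors, whose
basins are the clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CorrelationGraph",
    "ClusterSet",
    "build_graph",
    "prefilter_tagspm",
    "mcl",
    "cluster_report",
    "CAGE_PRESET",
]

# promoter-level (CAGE) parameterization: lower threshold, activity floor,
# smaller minimum reported cluster
CAGE_PRESET = {"threshold": 0.75, "tagspm_floor": 10.0, "min_cluster_size": 10}


@dataclass
class CorrelationGraph:
    """An undirected weighted graph of above-threshold correlations."""

    graph: nx.Graph
    threshold: float

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class ClusterSet:
    """Disjoint clusters covering every node; ids ordered by size."""

    clusters: dict[int, list[str]]
    inflation: float
    converged: bool = True
    min_reported_size: int = 1

    def membership(self) -> pd.Series:
        rows = {g: cid for cid, genes in self.clusters.items() for g in genes}
        return pd.Series(rows, name="cluster_id")

    def assert_partition(self, nodes) -> None:
        seen: set[str] = set()
        for members in self.clusters.values():
            m = set(members)
            if m & seen:
                raise AssertionError("clusters overlap")
            seen |= m
        if seen != set(nodes):
            raise AssertionError("clusters do not cover the node set")


def prefilter_tagspm(values: pd.DataFrame, floor: float = 10.0) -> pd.DataFrame:
    """Drop promoters whose activity never exceeds ``floor`` tags per million."""
    return values[values.max(axis=1) > floor]


def build_graph(corr: pd.DataFrame, threshold: float) -> CorrelationGraph:
    """Connect node pairs whose correlation is at or above the threshold.

    Undefined (NaN) correlations never create edges.  All nodes are kept,
    so below-threshold nodes appear as singletons.
    """
    if not (-1.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (-1, 1]")
    if list(corr.index) != list(corr.columns):
        raise ValueError("correlation matrix must be square with matching labels")
    g = nx.Graph()
    g.add_nodes_from(corr.index)
    m = corr.to_numpy()
    iu, ju = np.triu_indices(len(corr), k=1)
    w = m[iu, ju]
    keep = ~np.isnan(w) & (w >= threshold)
    labels = corr.index.to_numpy()
    g.add_weighted_edges_from(
        (labels[i], labels[j], float(x)) for i, j, x in zip(iu[keep], ju[keep], w[keep])
    )
    return CorrelationGraph(g, threshold)


def _mcl_matrix(
    M: np.ndarray, inflation: float, prune: float, tol: float, max_iter: int
) -> tuple[np.ndarray, bool]:
    """Iterate expansion/inflation on a column-stochastic matrix."""

    def normalize(A: np.ndarray) -> np.ndarray:
        s = A.sum(axis=0)
        s[s == 0] = 1.0
        return A / s

    M = normalize(M)
    converged = False
    for _ in range(max_iter):
        new = M @ M                      # expansion
        np.power(new, inflation, out=new)  # inflation
        new = normalize(new)
        # prune tiny entries, but never a column's maximum
        col_max = new.max(axis=0)
        new[(new < prune) & (new < col_max)] = 0.0
        new = normalize(new)
        if np.max(np.abs(new - M)) < tol:
            M = new
            converged = True
            break
        M = new
    return M, converged


def mcl(
    cgraph: CorrelationGraph | nx.Graph,
    inflation: float = 2.2,
    *,
    weighted: bool = True,
    prune: float = 1e-5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> ClusterSet:
    """Markov clustering of a correlation graph.

    Self-loops are added with weight equal to each node's maximum incident
    edge weight (1 for isolated nodes), the matrix is column-normalized,
    and expansion/inflation iterated with pruning until the column-wise
    maximum change falls below ``tol`` (or ``max_iter`` is hit, in which
    case the current matrix is interpreted and the result flagged
    non-converged).  Attractors are the nodes with positive return
    probability; attractors sharing a basin member form one cluster, and
    every other node joins the cluster to which its total attachment is
    strongest (ties to the lower cluster index).
    """
    g = cgraph.graph if isinstance(cgraph, CorrelationGraph) else cgraph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = float(data.get("weight", 1.0)) if weighted else 1.0
        A[index[u], index[v]] = A[index[v], index[u]] = w
    loop = A.max(axis=0)
    loop[loop == 0] = 1.0
    A[np.diag_indices(n)] = loop

    M, converged = _mcl_matrix(A, inflation, prune, tol, max_iter)

    eps = 1e-7
    attractors = [i for i in range(n) if M[i, i] > eps]
    # group attractors that serve a common node into one attractor system
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for j in range(n):
        served = [i for i in attractors if M[i, j] > eps]
        for a, b in zip(served, served[1:]):
            union(a, b)

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)
    system_ids = sorted(systems)

    members: dict[int, list[int]] = {sid: [] for sid in system_ids}
    orphans: list[int] = []
    for j in range(n):
        best_sid, best_w = None, 0.0
        for sid in system_ids:
            w = sum(M[a, j] for a in systems[sid])
            if w > best_w + 0.0:  # strict: ties stay with the lower (earlier) index
                best_sid, best_w = sid, w
        if best_sid is None or best_w <= eps:
            orphans.append(j)
        else:
            members[best_sid].append(j)

    raw: list[list[str]] = [sorted(nodes[i] for i in mem) for mem in members.values() if mem]
    raw += [[nodes[j]] for j in orphans]
    raw.sort(key=lambda c: (-len(c), c))
    clusters = {cid: mem for cid, mem in enumerate(raw, start=1)}
    cs = ClusterSet(clusters, inflation, converged)
    cs.assert_partition(nodes)
    return cs


def cluster_report(
    clusters: ClusterSet, pem_table, min_size: int = 26
) -> pd.DataFrame:
    """Summarise clusters of at least ``min_size`` members.

    For each reported cluster: size, the modal tissue in which members
    reach their highest PEM, and the fraction of members peaking there.
    """
    from .atlas import top_pem_tissue

    rows = []
    for cid, genes in clusters.clusters.items():
        if len(genes) < min_size:
            continue
        fractions, _ = top_pem_tissue(pem_table, genes)
        top = fractions.idxmax()
        rows.append(
            {
                "cluster_id": cid,
                "size": len(genes),
                "top_tissue": top,
                "fraction": float(fractions.loc[top]),
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "size", "top_tissue", "fraction"])
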