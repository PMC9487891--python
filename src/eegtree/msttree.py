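"""Minimum spanning tree construction and topology metrics.

The MST of a PLI adjacency matrix under link weight 1/PLI is the unique
acyclic subgraph connecting all electrodes through the strongest
couplings.  Construction is Kruskal's algorithm with a deterministic tie
rule (ascending distance, then ascending node indices); real-valued PLI
ties are measure-zero, so the rule matters only for degenerate synthetic
input.  Zero-PLI entries receive distance 1/eps (eps = 1e-12 by default)
instead of being excluded: connectivity is then guaranteed, and such an
edge is never chosen while any positive-PLI alternative exists.

The metric panel summarises each tree's balance between integration
(star-like: high leaf number, kappa) and overload of central nodes (high
betweenness):

==================  ====================================================
degree_max          largest node degree k_max
leaf                number of degree-1 nodes L
diameter            longest shortest path (hop count)
reported_diameter   N + 1 - L, a leaf-complement compatibility value
                    (see note below)
eccentricity_mean   mean over nodes of the longest hop distance
radius              smallest node eccentricity
strength_max/mean   node strength = sum of incident PLI weights
bc_max/median       betweenness: raw count of unordered node pairs whose
                    unique tree path passes through the node
cc_max/median       closeness: 1 / (sum of hop distances to all others)
kappa               <k^2> / <k>, broadness of the degree distribution
tree_hierarchy      Th = L / (2 * M * bc_max), M = N - 1 links
==================  ====================================================

``reported_diameter`` exists because a widely used convention reports the
quantity N + 1 - L under the name "diameter"; it always complements the
leaf number to N + 1 and can exceed twice the radius, so it is not the
graph-theoretic diameter, which this module reports separately.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from statistics import median
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "SpanningTree",
    "MSTMetrics",
    "build_mst",
    "tree_metrics",
    "tree_hierarchy",
    "aggregate_subject",
    "METRIC_NAMES",
]

#: Floor applied to PLI before inverting to a distance.
DEFAULT_EPS = 1e-12


@dataclass
class SpanningTree:
    """An MST as an edge list ``(i, j, pli)`` over ``n_nodes`` nodes."""

    n_nodes: int
    edges: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        if len(self.edges) != self.n_nodes - 1:
            raise ValueError(
                f"a spanning tree on {self.n_nodes} nodes needs "
                f"{self.n_nodes - 1} edges, got {len(self.edges)}"
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def distances(self, eps: float = DEFAULT_EPS) -> list[float]:
        """Per-edge distance 1/PLI (with the eps floor)."""
        return [1.0 / max(w, eps) for _, _, w in self.edges]

    def total_distance(self, eps: float = DEFAULT_EPS) -> float:
        return float(sum(self.distances(eps)))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for i, j, w in self.edges:
            g.add_edge(i, j, pli=w, distance=1.0 / max(w, DEFAULT_EPS))
        return g


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def build_mst(matrix: np.ndarray, eps: float = DEFAULT_EPS) -> SpanningTree:
    """Kruskal MST of a symmetric PLI matrix under distance 1/PLI.

    Edges are sorted by ascending distance with ties broken by ascending
    ``(i, j)``; edges are added unless they would close a cycle, until
    N - 1 edges connect all nodes.  Equivalently the result maximises the
    total PLI over all spanning trees.

    Raises
    ------
    ValueError
        If the matrix is not square/symmetric, N < 2, or every
        off-diagonal entry is zero (no coupling information at all).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("matrix must be symmetric")
    if np.any(m < -1e-12):
        raise ValueError("PLI values must be non-negative")
    iu, ju = np.triu_indices(n, k=1)
    w = m[iu, ju]
    if not np.any(w > 0):
        raise ValueError("all PLI entries are zero; no spanning tree is meaningful")
    dist = 1.0 / np.maximum(w, eps)
    order = np.lexsort((ju, iu, dist))  # distance, then i, then j ascending
    uf = _UnionFind(n)
    edges: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        if uf.union(i, j):
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    return SpanningTree(n, edges)


@dataclass
class MSTMetrics:
    """The tree topology metric panel (one tree, or an epoch average)."""

    degree_max: float
    leaf: float
    diameter: float
    reported_diameter: float
    eccentricity_mean: float
    radius: float
    strength_max: float
    strength_mean: float
    bc_max: float
    bc_median: float
    cc_max: float
    cc_median: float
    kappa: float
    tree_hierarchy: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


#: Column order of the metric panel.
METRIC_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclass_fields(MSTMetrics)
)


def tree_hierarchy(leaf: float, n_links: float, bc_max: float) -> float:
    """Th = L / (2 * M * BC_max): integration vs. central-node overload."""
    if bc_max <= 0 or n_links <= 0:
        return float("nan")
    return leaf / (2.0 * n_links * bc_max)


def tree_metrics(t: SpanningTree) -> MSTMetrics:
    """Compute the full metric panel for one spanning tree.

    Hop (unweighted) distances are used for diameter, eccentricity,
    radius, betweenness and closeness; PLI weights are used for strength.
    Betweenness is the raw count of unordered node pairs routed through
    each node (the unique tree path), not normalized.
    """
    n = t.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    g = t.graph()

    deg = np.array([d for _, d in g.degree()], dtype=float)
    leaf = float((deg == 1).sum())
    kappa = float((deg**2).mean() / deg.mean())

    strength = np.zeros(n)
    for i, j, w in t.edges:
        strength[i] += w
        strength[j] += w

    ecc = nx.eccentricity(g)  # hop-based on an unweighted graph
    ecc_vals = np.array([ecc[v] for v in range(n)], dtype=float)
    diameter = float(ecc_vals.max())
    radius = float(ecc_vals.min())

    bc = nx.betweenness_centrality(g, normalized=False)
    bc_vals = np.array([bc[v] for v in range(n)], dtype=float)

    # closeness as the plain inverse summed hop distance (no (n-1) scaling)
    cc_vals = np.empty(n)
    for v in range(n):
        dist_sum = sum(nx.single_source_shortest_path_length(g, v).values())
        cc_vals[v] = 1.0 / dist_sum if dist_sum > 0 else float("nan")

    m_links = n - 1
    return MSTMetrics(
        degree_max=float(deg.max()),
        leaf=leaf,
        diameter=diameter,
        reported_diameter=float(n + 1 - leaf),
        eccentricity_mean=float(ecc_vals.mean()),
        radius=radius,
        strength_max=float(strength.max()),
        strength_mean=float(strength.mean()),
        bc_max=float(bc_vals.max()),
        bc_median=float(np.median(bc_vals)),
        cc_max=float(np.nanmax(cc_vals)),
        cc_median=float(np.nanmedian(cc_vals)),
        kappa=kappa,
        tree_hierarchy=tree_hierarchy(leaf, m_links, float(bc_vals.max())),
    )


def aggregate_subject(metrics: Sequence[MSTMetrics]) -> MSTMetrics:
    """Arithmetic mean of each panel field across epochs.

    One subject/condition/band at a time; mixing bands or conditions in a
    single aggregate is the caller's error to avoid (the panel itself
    carries no band tag).
    """
    if len(metrics) == 0:
        raise ValueError("no epoch metrics to aggregate")
    acc = {name: float(np.mean([m.as_dict()[name] for m in metrics]))
           for name in METRIC_NAMES}
    return MSTMetrics(**acc)
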