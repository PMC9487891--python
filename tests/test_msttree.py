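"""MST construction against exhaustive oracles, and the metric panel
against hand computations and brute-force path counting."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from eegtree.msttree import (
    METRIC_NAMES,
    MSTMetrics,
    SpanningTree,
    aggregate_subject,
    build_mst,
    tree_hierarchy,
    tree_metrics,
)

from conftest import random_pli_matrix


# ---------------------------------------------------------------- oracles
def exhaustive_min_tree_distance(m):
    """Minimum total 1/PLI over all spanning trees, by brute enumeration."""
    n = m.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for subset in combinations(edges, n - 1):
        g = nx.Graph(subset)
        if g.number_of_nodes() == n and nx.is_connected(g):
            total = sum(1.0 / m[i, j] for i, j in subset)
            best = min(best, total)
    return best


def brute_force_betweenness(tree: SpanningTree):
    """Count, per node, unordered pairs whose unique tree path crosses it."""
    g = tree.graph()
    counts = {v: 0 for v in g.nodes}
    for s, t in combinations(sorted(g.nodes), 2):
        path = nx.shortest_path(g, s, t)
        for v in path[1:-1]:
            counts[v] += 1
    return counts


def random_tree(rng, n):
    g = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    edges = [(min(i, j), max(i, j), float(rng.uniform(0.1, 1.0)))
             for i, j in g.edges]
    return SpanningTree(n, edges)


# ------------------------------------------------------------ build_mst
def test_kruskal_matches_exhaustive_enumeration(rng):
    for _ in range(60):
        n = int(rng.integers(3, 8))
        m = random_pli_matrix(rng, n)
        tree = build_mst(m)
        assert tree.n_edges == n - 1
        assert np.isclose(tree.total_distance(),
                          exhaustive_min_tree_distance(m))


def test_kruskal_matches_networkx_on_larger_graphs(rng):
    for _ in range(10):
        n = int(rng.integers(20, 40))
        m = random_pli_matrix(rng, n)
        tree = build_mst(m)
        g = nx.Graph()
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(i, j, weight=1.0 / m[i, j])
        ref = nx.minimum_spanning_tree(g, algorithm="kruskal")
        assert np.isclose(tree.total_distance(),
                          ref.size(weight="weight"))


def test_four_node_example_selects_strongest_chain():
    # strongest couplings form the path 0-1-2-3; verified by enumeration
    m = np.zeros((4, 4))
    for (i, j), v in {(0, 1): 0.9, (1, 2): 0.8, (2, 3): 0.7,
                      (0, 2): 0.1, (0, 3): 0.2, (1, 3): 0.3}.items():
        m[i, j] = m[j, i] = v
    tree = build_mst(m)
    assert sorted((i, j) for i, j, _ in tree.edges) == [(0, 1), (1, 2), (2, 3)]
    assert np.isclose(tree.total_distance(), exhaustive_min_tree_distance(m))


def test_two_node_tree_distance():
    m = np.array([[0.0, 0.5], [0.5, 0.0]])
    tree = build_mst(m)
    assert tree.edges == [(0, 1, 0.5)]
    assert tree.distances() == [2.0]


def test_equal_weight_ties_break_by_index_order():
    m = random_pli_matrix(np.random.default_rng(0), 6)
    m[m > 0] = 0.5  # all ties -> Kruskal takes (0,1), (0,2), ... (0,5)
    tree = build_mst(m)
    assert sorted((i, j) for i, j, _ in tree.edges) == [(0, k) for k in range(1, 6)]


def test_zero_pli_entries_floored_not_excluded():
    # node 3 has zero PLI to everyone: still spanned, via an epsilon edge
    m = random_pli_matrix(np.random.default_rng(1), 5)
    m[3, :] = m[:, 3] = 0.0
    tree = build_mst(m)
    assert tree.n_edges == 4
    assert any(3 in (i, j) for i, j, _ in tree.edges)
    with pytest.raises(ValueError):
        build_mst(np.zeros((4, 4)))


def test_build_mst_input_validation(rng):
    with pytest.raises(ValueError):
        build_mst(np.zeros((1, 1)))
    with pytest.raises(ValueError):
        build_mst(np.arange(9.0).reshape(3, 3))  # asymmetric


# ---------------------------------------------------------- tree_metrics
def test_path_graph_hand_values():
    tree = SpanningTree(4, [(0, 1, 0.5), (1, 2, 0.5), (2, 3, 0.5)])
    m = tree_metrics(tree)
    assert m.leaf == 2
    assert m.diameter == 3
    assert m.radius == 2
    assert np.isclose(m.kappa, 10 / 6)
    assert m.bc_max == 2
    assert np.isclose(m.tree_hierarchy, 2 / (2 * 3 * 2))
    assert m.reported_diameter == 4 + 1 - 2


def test_star_graph_hand_values():
    tree = SpanningTree(5, [(0, k, 0.5) for k in range(1, 5)])
    m = tree_metrics(tree)
    assert m.leaf == 4
    assert m.diameter == 2
    assert m.radius == 1
    assert np.isclose(m.kappa, 2.5)
    assert m.bc_max == 6  # C(4, 2) pairs through the hub
    assert np.isclose(m.tree_hierarchy, 4 / (2 * 4 * 6))


def test_tree_hierarchy_from_group_mean_panel_values():
    # a 120-node tree panel: Th must equal L / (2 M BCmax) to 2 sig figs
    th = tree_hierarchy(leaf=66.837, n_links=119, bc_max=4698)
    assert abs(th - 6.0e-5) < 0.05e-5


def test_betweenness_matches_brute_force(rng):
    for _ in range(25):
        n = int(rng.integers(4, 51))
        tree = random_tree(rng, n)
        expected = brute_force_betweenness(tree)
        m = tree_metrics(tree)
        vals = np.array(sorted(expected.values()), dtype=float)
        assert m.bc_max == vals.max()
        assert np.isclose(m.bc_median, np.median(vals))


def test_metric_invariants_on_random_trees(rng):
    for _ in range(30):
        n = int(rng.integers(3, 40))
        tree = random_tree(rng, n)
        m = tree_metrics(tree)
        g = tree.graph()
        degrees = np.array([d for _, d in g.degree()], dtype=float)
        assert degrees.sum() == 2 * (n - 1)
        assert 2 <= m.leaf <= n - 1
        assert m.kappa >= degrees.mean() - 1e-12
        assert m.radius <= m.eccentricity_mean <= m.diameter <= 2 * m.radius
        assert np.isclose(m.tree_hierarchy * 2 * (n - 1) * m.bc_max, m.leaf)
        ecc = nx.eccentricity(g)
        assert m.diameter == max(ecc.values())
        assert m.radius == min(ecc.values())
        # strength uses PLI weights: bounded by degree since PLI <= 1
        assert m.strength_max <= degrees.max()


def test_path_and_star_are_topology_extremes(rng):
    n = 10
    path = SpanningTree(n, [(k, k + 1, 0.5) for k in range(n - 1)])
    star = SpanningTree(n, [(0, k, 0.5) for k in range(1, n)])
    mp, ms = tree_metrics(path), tree_metrics(star)
    assert ms.leaf == n - 1
    assert np.isclose(ms.kappa, n / 2)
    for _ in range(20):
        m = tree_metrics(random_tree(rng, n))
        assert mp.leaf <= m.leaf <= ms.leaf
        assert mp.kappa - 1e-9 <= m.kappa <= ms.kappa + 1e-9


# ------------------------------------------------------------- aggregate
def test_aggregate_subject_is_elementwise_mean():
    tree = SpanningTree(4, [(0, 1, 0.5), (1, 2, 0.5), (2, 3, 0.5)])
    m = tree_metrics(tree)
    same = aggregate_subject([m, m, m])
    assert same.as_dict() == pytest.approx(m.as_dict())

    a = m.as_dict()
    b = dict(a)
    a["leaf"], b["leaf"] = 60.0, 70.0
    agg = aggregate_subject([MSTMetrics(**a), MSTMetrics(**b)])
    assert agg.leaf == 65.0

    with pytest.raises(ValueError):
        aggregate_subject([])


def test_epoch_averaging_shrinks_leaf_spread(rng):
    # SE of the 18-epoch mean should shrink roughly as 1/sqrt(18)
    def leafs(n_epochs, n_rep):
        out = []
        for _ in range(n_rep):
            ms = [tree_metrics(build_mst(random_pli_matrix(rng, 20)))
                  for _ in range(n_epochs)]
            out.append(aggregate_subject(ms).leaf)
        return np.std(out)

    single = leafs(1, 40)
    averaged = leafs(18, 40)
    ratio = averaged / single
    assert 0.5 / np.sqrt(18) < ratio < 2.0 / np.sqrt(18)
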