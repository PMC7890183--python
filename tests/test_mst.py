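"""Spanning-tree extraction and integration metrics vs exhaustive oracles."""

from itertools import product

import numpy as np
import pytest

from balancenet.core import DataError
from balancenet.mst import (
    SpanningTree,
    aggregate_metrics,
    avg_eccentricity,
    bc_max,
    leaf_fraction,
    max_spanning_tree,
    tree_diameter,
    tree_metrics,
    TreeMetrics,
)

# ---------------------------------------------------------------- oracles


def prufer_to_edges(seq, n):
    """Decode a Pruefer sequence into the edge list of a labeled tree."""
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    seq = list(seq)
    for v in seq:
        leaf = min(i for i in range(n) if degree[i] == 1)
        edges.append((min(leaf, v), max(leaf, v)))
        degree[leaf] -= 1
        degree[v] -= 1
    u, w = [i for i in range(n) if degree[i] == 1]
    edges.append((u, w))
    return edges


def all_trees(n):
    """Every labeled tree on n nodes (Cayley: n^(n-2) of them)."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in product(range(n), repeat=n - 2):
        yield prufer_to_edges(seq, n)


def bfs_dists(adj, src, n):
    dist = [-1] * n
    dist[src] = 0
    queue = [src]
    while queue:
        u = queue.pop(0)
        for v in adj[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_metrics(edges, n):
    """All four metrics by explicit BFS / path enumeration (normalized)."""
    adj = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    dists = [bfs_dists(adj, s, n) for s in range(n)]
    ecc = [max(d) for d in dists]
    diam = max(ecc) / (n - 1)
    avg_ecc = sum(ecc) / n / (n - 1)
    leaves = sum(1 for i in range(n) if len(adj[i]) == 1)
    lf = leaves / (n - 1)
    # betweenness by walking the unique path of every pair
    counts = [0] * n
    parent_of = {}
    for s in range(n):
        parent = [-1] * n
        queue = [s]
        seen = {s}
        while queue:
            u = queue.pop(0)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    parent[v] = u
                    queue.append(v)
        parent_of[s] = parent
    for s in range(n):
        for t in range(s + 1, n):
            v = parent_of[s][t]
            while v != s and v != -1:
                counts[v] += 1
                v = parent_of[s][v]
    bc = (
        max(counts) / ((n - 1) * (n - 2) / 2) if n >= 3 else float("nan")
    )
    return diam, lf, avg_ecc, bc


def spanning_tree_max_weight(w):
    """Exhaustive maximum over all labeled spanning trees."""
    n = w.shape[0]
    best = -np.inf
    for edges in all_trees(n):
        best = max(best, sum(w[i, j] for i, j in edges))
    return best


# ------------------------------------------------------------------ tests


class TestMaxSpanningTree:
    def test_three_node_example_drops_weakest_closing_edge(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.1
        t = max_spanning_tree(w)
        assert sorted((i, j) for i, j, _ in t.edges) == [(0, 1), (0, 2)]

    def test_equal_weights_tie_break_is_lexicographic_and_stable(self):
        w = np.ones((5, 5)) - np.eye(5)
        t1 = max_spanning_tree(w)
        t2 = max_spanning_tree(w)
        assert t1.edges == t2.edges
        # Kruskal on equal weights in (i, j) order picks the star at node 0
        assert sorted((i, j) for i, j, _ in t1.edges) == [
            (0, 1), (0, 2), (0, 3), (0, 4)
        ]

    @pytest.mark.parametrize("seed", range(10))
    def test_total_weight_matches_exhaustive_optimum(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((6, 6))
        w = np.triu(w, 1)
        w = w + w.T
        t = max_spanning_tree(w)
        assert t.total_weight() == pytest.approx(
            spanning_tree_max_weight(w), abs=1e-12
        )

    def test_disconnected_positive_graph_falls_back_with_warning(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5  # nodes 2, 3 unreachable by positive edges
        with pytest.warns(UserWarning, match="zero-weight"):
            t = max_spanning_tree(w)
        assert len(t.edges) == 3

    def test_single_node_rejected(self):
        with pytest.raises(DataError):
            max_spanning_tree(np.zeros((1, 1)))


def path_tree(n):
    return SpanningTree(n, [(i, i + 1, 1.0) for i in range(n - 1)])


def star_tree(n):
    return SpanningTree(n, [(0, i, 1.0) for i in range(1, n)])


class TestMetricClosedForms:
    def test_path_graph(self):
        t = path_tree(30)
        assert tree_diameter(t) == 1.0
        assert leaf_fraction(t) == pytest.approx(2 / 29)

    def test_star_graph(self):
        n = 10
        t = star_tree(n)
        assert tree_diameter(t) == pytest.approx(2 / (n - 1))
        assert leaf_fraction(t) == 1.0
        # center eccentricity 1, each of the n-1 leaves 2
        assert avg_eccentricity(t) == pytest.approx(
            (1 + 2 * (n - 1)) / (n * (n - 1))
        )
        assert bc_max(t) == 1.0

    def test_five_node_path_middle_betweenness(self):
        # pairs (0,3),(0,4),(1,3),(1,4) cross node 2 -> 4 of 6 pairs
        assert bc_max(path_tree(5)) == pytest.approx(4 / 6)

    def test_two_node_path_diameter(self):
        assert tree_diameter(path_tree(2)) == 1.0

    def test_unnormalized_variants(self):
        t = path_tree(5)
        assert tree_diameter(t, normalize=False) == 4
        assert avg_eccentricity(t, normalize=False) == pytest.approx(
            (4 + 3 + 2 + 3 + 4) / 5
        )


class TestOracleEquivalence:
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_all_small_trees_match_bfs_oracle(self, n):
        for edges in all_trees(n):
            t = SpanningTree(n, [(i, j, 1.0) for i, j in edges])
            got = (
                tree_diameter(t), leaf_fraction(t), avg_eccentricity(t),
            )
            exp = oracle_metrics(edges, n)
            assert got == pytest.approx(exp[:3], abs=1e-12)
            if n >= 3:
                assert bc_max(t) == pytest.approx(exp[3], abs=1e-12)

    def test_metrics_independent_of_edge_weights(self, rng):
        edges = prufer_to_edges((2, 2, 4, 1), 6)
        t1 = SpanningTree(6, [(i, j, 1.0) for i, j in edges])
        t2 = SpanningTree(6, [(i, j, w) for (i, j), w in
                              zip(edges, rng.random(5))])
        assert tree_metrics(t1) == tree_metrics(t2)


class TestIntegrationDirection:
    def test_path_to_star_morph_is_monotone(self):
        """Re-rooting path nodes onto a hub must monotonically raise
        leaf fraction and BC_max and lower diameter and eccentricity."""
        n = 12
        prev = None
        for k in range(1, n):
            # nodes 1..k hang off the hub, the rest continue as a chain
            edges = [(0, i, 1.0) for i in range(1, k + 1)]
            edges += [(i, i + 1, 1.0) for i in range(k, n - 1)]
            t = SpanningTree(n, edges)
            m = tree_metrics(t)
            if prev is not None:
                assert m.leaf_fraction >= prev.leaf_fraction - 1e-12
                assert m.bc_max >= prev.bc_max - 1e-12
                assert m.diameter <= prev.diameter + 1e-12
                assert m.avg_eccentricity <= prev.avg_eccentricity + 1e-12
            prev = m


class TestAggregation:
    def test_identical_trees_equal_single_value(self):
        m = tree_metrics(star_tree(8))
        agg = aggregate_metrics([m, m, m])
        assert agg == m

    def test_two_epoch_mean(self):
        a = TreeMetrics(0.2, 0.2, 0.2, 0.2)
        b = TreeMetrics(0.4, 0.4, 0.4, 0.4)
        agg = aggregate_metrics([a, b])
        assert agg.diameter == pytest.approx(0.3)

    def test_trials_weighted_equally_despite_epoch_counts(self):
        a = TreeMetrics(0.0, 0.0, 0.0, 0.0)
        b = TreeMetrics(1.0, 1.0, 1.0, 1.0)
        # trial 1 has 3 epochs of a, trial 2 a single b: per-trial-then-
        # average gives 0.5, the pooled mean would give 0.25
        agg = aggregate_metrics([[a, a, a], [b]])
        assert agg.diameter == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            aggregate_metrics([])
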