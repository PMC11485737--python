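import itertools

import networkx as nx
import numpy as np
import pytest

from castream import network
from castream.network import (
    CorrelationMatrix,
    WindowTooShortError,
    mst_network,
    pairwise_correlations,
    rank_by_degree,
    ranking_stability,
    threshold_network,
)


def _corr_formula_oracle(a, b):
    """The printed correlation formula by direct summation."""
    n = len(a)
    mu_a, mu_b = sum(a) / n, sum(b) / n
    sd_a = (sum((x - mu_a) ** 2 for x in a) / (n - 1)) ** 0.5
    sd_b = (sum((x - mu_b) ** 2 for x in b) / (n - 1)) ** 0.5
    return sum((a[i] - mu_a) / sd_a * ((b[i] - mu_b) / sd_b) for i in range(n)) / (n - 1)


def _random_corr(rng, n):
    dff = rng.standard_normal((120, n))
    return pairwise_correlations(dff)


class TestPairwiseCorrelations:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(100)
        corr = pairwise_correlations(np.column_stack([x, x]))
        assert corr.rho[0, 1] == pytest.approx(1.0)
        assert corr.rho[0, 0] == 1.0

    def test_negation_gives_minus_one(self, rng):
        x = rng.standard_normal(100)
        corr = pairwise_correlations(np.column_stack([x, -x]))
        assert corr.rho[0, 1] == pytest.approx(-1.0)

    def test_matches_printed_formula_oracle(self, rng):
        dff = rng.standard_normal((100, 2))
        corr = pairwise_correlations(dff)
        expected = _corr_formula_oracle(list(dff[:, 0]), list(dff[:, 1]))
        assert abs(corr.rho[0, 1] - expected) < 1e-12

    def test_zero_variance_trace_undefined(self, rng):
        dff = np.column_stack([rng.standard_normal(50), np.full(50, 3.0)])
        corr = pairwise_correlations(dff)
        assert np.isnan(corr.rho[0, 1]) and np.isnan(corr.rho[1, 1])
        assert corr.rho[0, 0] == 1.0

    def test_short_window_withheld(self, rng):
        with pytest.raises(WindowTooShortError):
            pairwise_correlations(rng.standard_normal((10, 3)), min_samples=30)

    def test_location_and_scale_invariance(self, rng):
        dff = rng.standard_normal((80, 4))
        base = pairwise_correlations(dff).rho
        shifted = pairwise_correlations(dff + 7.3).rho
        scaled = pairwise_correlations(dff * 2.5).rho
        np.testing.assert_allclose(base, shifted, atol=1e-10)
        np.testing.assert_allclose(base, scaled, atol=1e-10)


def _all_spanning_trees(n):
    """All spanning trees of K_n as edge-index tuples (brute force)."""
    edges = list(itertools.combinations(range(n), 2))
    trees = []
    for combo in itertools.combinations(range(len(edges)), n - 1):
        g = nx.Graph([edges[i] for i in combo])
        if g.number_of_nodes() == n and nx.is_connected(g):
            trees.append(combo)
    return edges, trees


class TestMst:
    def test_three_node_example(self):
        rho = np.array([[1.0, 0.9, 0.5], [0.9, 1.0, 0.1], [0.5, 0.1, 1.0]])
        corr = CorrelationMatrix(rho=rho, cell_ids=[0, 1, 2], window=(0, 100))
        graph = mst_network(corr)
        assert {(i, j) for i, j, _, _ in graph.edges} == {(0, 1), (0, 2)}
        # exhaustive check over all 3 spanning trees
        weights = {(0, 1): 0.1, (0, 2): 0.5, (1, 2): 0.9}
        tree_weights = [
            weights[(0, 1)] + weights[(0, 2)],
            weights[(0, 1)] + weights[(1, 2)],
            weights[(0, 2)] + weights[(1, 2)],
        ]
        got = sum(w for _, _, _, w in graph.edges)
        assert got == pytest.approx(min(tree_weights))

    def test_invariants_and_minimality_vs_exhaustive(self, rng):
        for n in (4, 5, 6):
            corr = _random_corr(rng, n)
            graph = mst_network(corr)
            assert graph.n_edges == n - 1
            g = nx.Graph([(i, j) for i, j, _, _ in graph.edges])
            assert nx.is_connected(g) and nx.is_forest(g)
            edges, trees = _all_spanning_trees(n)
            wmap = {e: 1 - abs(corr.rho[e[0], e[1]]) for e in edges}
            best = min(sum(wmap[edges[i]] for i in t) for t in trees)
            got = sum(w for _, _, _, w in graph.edges)
            assert got == pytest.approx(best, abs=1e-12)

    def test_matches_networkx_mst_weight(self, rng):
        """Independent library oracle for the total tree weight."""
        corr = _random_corr(rng, 12)
        graph = mst_network(corr)
        g = nx.Graph()
        for a in range(12):
            for b in range(a + 1, 12):
                g.add_edge(a, b, weight=1 - abs(corr.rho[a, b]))
        expected = nx.minimum_spanning_tree(g).size(weight="weight")
        assert sum(w for *_, w in graph.edges) == pytest.approx(expected, abs=1e-12)

    def test_undefined_correlations_connect_last(self, rng):
        dff = np.column_stack([rng.standard_normal((60, 3)), np.full((60, 1), 2.0)])
        corr = pairwise_correlations(dff)
        graph = mst_network(corr)
        assert graph.n_edges == 3  # flat cell still connected
        flat_edges = [e for e in graph.edges if 3 in (e[0], e[1])]
        assert len(flat_edges) == 1 and flat_edges[0][3] == 1.0

    def test_fewer_than_two_nodes_empty(self):
        corr = CorrelationMatrix(rho=np.array([[1.0]]), cell_ids=[0], window=(0, 10))
        assert mst_network(corr).n_edges == 0


class TestThreshold:
    def test_theta_zero_complete_graph(self, rng):
        corr = _random_corr(rng, 6)
        graph = threshold_network(corr, 0.0)
        assert graph.n_edges == 15
        assert all(d == 5 for d in graph.degree.values())

    def test_theta_one_empty_on_perturbed(self, rng):
        corr = _random_corr(rng, 6)
        assert threshold_network(corr, 1.0).n_edges == 0

    def test_edge_set_matches_brute_force_filter(self, rng):
        corr = _random_corr(rng, 8)
        graph = threshold_network(corr, 0.5)
        expected = {
            (min(a, b), max(a, b))
            for a in range(8)
            for b in range(a + 1, 8)
            if abs(corr.rho[a, b]) >= 0.5
        }
        assert {(i, j) for i, j, _, _ in graph.edges} == expected


class TestRanking:
    def test_star_center_ranks_first(self):
        corr = CorrelationMatrix(
            rho=np.eye(4), cell_ids=[0, 1, 2, 3], window=(0, 10)
        )
        graph = network.FunctionalGraph(
            cell_ids=[0, 1, 2, 3],
            edges=[(0, 1, 0.9, 0.1), (0, 2, 0.9, 0.1), (0, 3, 0.9, 0.1)],
            method="mst",
        )
        assert rank_by_degree(graph)[0] == 0

    def test_path_graph_interior_outranks_endpoints_ties_by_id(self):
        graph = network.FunctionalGraph(
            cell_ids=[0, 1, 2, 3],
            edges=[(0, 1, 0.5, 0.5), (1, 2, 0.5, 0.5), (2, 3, 0.5, 0.5)],
            method="mst",
        )
        assert rank_by_degree(graph) == [1, 2, 0, 3]

    def test_matches_independent_sort_oracle(self, rng):
        corr = _random_corr(rng, 10)
        graph = threshold_network(corr, 0.1)
        ranking = rank_by_degree(graph)
        expected = [
            c for _, c in sorted(
                ((-graph.degree[c], c) for c in graph.cell_ids)
            )
        ]
        assert ranking == expected


class TestRankingStability:
    def test_identical_rankings_zero_percent(self):
        r = list(range(20))
        assert ranking_stability([r, r, r], k=10) == 0.0

    def test_disjoint_top_sets_hundred_percent(self):
        a = list(range(20))
        b = list(range(10, 20)) + list(range(10))
        assert ranking_stability([a, b, a, b], k=10) == 100.0

    def test_random_signals_show_high_turnover(self, rng):
        """Surrogate random-signal datasets show turnover near the random-control level."""
        turnovers = []
        for _ in range(10):
            dff = rng.standard_normal((400, 20))
            rankings = []
            for end in range(100, 401, 50):
                corr = pairwise_correlations(dff[:end])
                rankings.append(rank_by_degree(mst_network(corr)))
            turnovers.append(ranking_stability(rankings, k=10))
        # random signals: large turnover, far from stable (0%)
        assert np.mean(turnovers) > 20.0
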