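"""Graph construction, efficiency family, null models and small-world logic."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from econets import (
    AdjacencyGraph,
    MetricCurve,
    build_null_ensemble,
    clustering_and_pathlength,
    cost_efficiency_curve,
    default_cost_grid,
    global_efficiency,
    local_efficiency,
    metric_curves,
    nodal_efficiency,
    random_graph_matched,
    regular_lattice_matched,
    shortest_path_lengths,
    sigma_small_worldness,
    small_world_regime,
    threshold_by_cost,
    watts_strogatz_matched,
)


# ---------------------------------------------------------------- oracles

def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def efficiency_oracle(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1)) if n > 1 else 0.0


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size >= 2:
            total += efficiency_oracle(adj[np.ix_(nbrs, nbrs)])
    return total / n


def clustering_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        k = nbrs.size
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            adj[u, v] for ai, u in enumerate(nbrs) for v in nbrs[ai + 1 :]
        )
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def random_adj(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


# ------------------------------------------------------------- thresholding

class TestThresholdByCost:
    def test_58_nodes_cost_016_gives_264_edges(self, rng):
        mi = random_adj(58, 0.5, rng) * rng.random((58, 58))
        mi = np.triu(rng.random((58, 58)), 1)
        mi = mi + mi.T
        g = threshold_by_cost(mi, 0.16)
        assert g.n_edges == 264
        assert round(2 * g.n_edges / 58) == 9

    def test_cost_one_gives_complete_graph(self, rng):
        mi = np.triu(rng.random((58, 58)), 1)
        g = threshold_by_cost(mi + mi.T, 1.0)
        assert g.n_edges == 58 * 57 // 2 == 1653

    def test_strongest_pairs_selected(self):
        mi = np.zeros((4, 4))
        mi[0, 1] = mi[1, 0] = 3.0
        mi[2, 3] = mi[3, 2] = 2.0
        mi[0, 2] = mi[2, 0] = 1.0
        g = threshold_by_cost(mi, 2 / 6)
        assert g.adj[0, 1] == 1 and g.adj[2, 3] == 1 and g.n_edges == 2

    def test_tie_break_by_index_deterministic(self):
        mi = np.ones((4, 4)) - np.eye(4)
        g = threshold_by_cost(mi, 2 / 6)
        # all values tie: lowest (row, col) pairs win -> (0,1) and (0,2)
        assert g.adj[0, 1] == 1 and g.adj[0, 2] == 1 and g.n_edges == 2

    def test_tiny_cost_gives_empty_graph(self):
        mi = np.triu(np.random.default_rng(0).random((10, 10)), 1)
        g = threshold_by_cost(mi + mi.T, 0.01)  # round(0.45) = 0 edges
        assert g.n_edges == 0

    def test_invalid_cost_rejected(self):
        with pytest.raises(ValueError):
            threshold_by_cost(np.zeros((3, 3)), 0.0)

    def test_nested_thresholds_monotone_metrics(self, rng):
        mi = np.triu(rng.random((20, 20)), 1)
        mi = mi + mi.T
        curves = metric_curves(mi, default_cost_grid(0.16, 0.5, 0.02))
        assert np.all(np.diff(curves["Eglob"].values) >= 0)
        # Elocal rises with cost overall, but single added edges may dilute a
        # neighbor subgraph, so only the trend is monotone
        el = curves["Elocal"].values
        assert el[-1] > el[0]
        assert np.mean(np.diff(el) >= 0) > 0.7


# ------------------------------------------------------------ shortest paths

class TestShortestPaths:
    def test_path_graph(self):
        g = AdjacencyGraph.from_edges(3, [(0, 1), (1, 2)])
        d = shortest_path_lengths(g)
        assert d[0, 2] == 2 and d[0, 1] == 1 and d[0, 0] == 0

    def test_disconnected_pair_is_inf(self):
        g = AdjacencyGraph(np.zeros((2, 2)))
        assert np.isinf(shortest_path_lengths(g)[0, 1])

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(50):
            adj = random_adj(int(rng.integers(4, 21)), rng.uniform(0.1, 0.6), rng)
            d = shortest_path_lengths(AdjacencyGraph(adj))
            np.testing.assert_array_equal(d, floyd_warshall(adj))


# ---------------------------------------------------------- efficiency family

class TestEfficiencyClosedForms:
    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_complete_graph_eglob_is_one(self, n):
        assert global_efficiency(AdjacencyGraph(1 - np.eye(n))) == 1.0

    def test_path3_eglob(self):
        g = AdjacencyGraph.from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(g) == pytest.approx(5 / 6)

    def test_edgeless_eglob_zero(self):
        assert global_efficiency(AdjacencyGraph(np.zeros((5, 5)))) == 0.0

    def test_star_center_and_leaf_enodal(self):
        g = AdjacencyGraph.from_edges(4, [(0, 1), (0, 2), (0, 3)])
        en = nodal_efficiency(g)
        assert en[0] == pytest.approx(1.0)
        assert en[1] == pytest.approx(2 / 3)  # distances 1, 2, 2

    def test_triangle_elocal_one(self):
        g = AdjacencyGraph.from_edges(3, [(0, 1), (1, 2), (0, 2)])
        assert local_efficiency(g) == pytest.approx(1.0)

    def test_path3_elocal_zero(self):
        g = AdjacencyGraph.from_edges(3, [(0, 1), (1, 2)])
        assert local_efficiency(g) == 0.0

    def test_k4_clustering_and_pathlength(self):
        cp, lp = clustering_and_pathlength(AdjacencyGraph(1 - np.eye(4)))
        assert cp == 1.0 and lp == 1.0

    def test_ring6_clustering_and_pathlength(self):
        g = AdjacencyGraph(nx.to_numpy_array(nx.cycle_graph(6)))
        cp, lp = clustering_and_pathlength(g)
        assert cp == 0.0 and lp == pytest.approx(1.8)

    def test_fully_disconnected_lp_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="disconnected"):
            _, lp = clustering_and_pathlength(AdjacencyGraph(np.zeros((4, 4))))
        assert np.isnan(lp)


class TestOracleEquivalence:
    def test_metrics_equal_brute_force_on_small_graphs(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 9))
            adj = random_adj(n, rng.uniform(0.1, 0.9), rng)
            g = AdjacencyGraph(adj)
            assert global_efficiency(g) == pytest.approx(efficiency_oracle(adj), abs=1e-12)
            assert local_efficiency(g) == pytest.approx(local_efficiency_oracle(adj), abs=1e-12)
            en = nodal_efficiency(g)
            assert en.mean() == pytest.approx(global_efficiency(g), abs=1e-12)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                cp, _ = clustering_and_pathlength(g) if n >= 3 else (0.0, 0.0)
            assert cp == pytest.approx(clustering_oracle(adj), abs=1e-12)

    def test_matches_networkx_on_moderate_graphs(self, rng):
        """Independent cross-check against networkx implementations."""
        for _ in range(10):
            adj = random_adj(15, 0.3, rng)
            g = AdjacencyGraph(adj)
            gx = g.to_networkx()
            assert global_efficiency(g) == pytest.approx(nx.global_efficiency(gx))
            assert clustering_and_pathlength(g)[0] == pytest.approx(nx.average_clustering(gx))


# ------------------------------------------------------------ cost-efficiency

class TestCostEfficiency:
    def test_pointwise_difference_and_argmax(self):
        curve = MetricCurve("Eglob", np.array([0.2, 0.5]), np.array([1.0, 1.0]))
        ce, maxce, at = cost_efficiency_curve(curve)
        np.testing.assert_allclose(ce.values, [0.8, 0.5])
        assert maxce == pytest.approx(0.8) and at == pytest.approx(0.2)

    def test_tie_resolves_to_lowest_cost(self):
        curve = MetricCurve("Eglob", np.array([0.2, 0.4]), np.array([0.5, 0.7]))
        _, maxce, at = cost_efficiency_curve(curve)
        assert maxce == pytest.approx(0.3) and at == pytest.approx(0.2)

    def test_complete_graph_ce_zero_at_cost_one(self):
        g = AdjacencyGraph(1 - np.eye(10))
        curve = MetricCurve("Eglob", np.array([1.0]), np.array([global_efficiency(g)]))
        _, maxce, _ = cost_efficiency_curve(curve)
        assert maxce == pytest.approx(0.0)

    def test_random_graph_is_economical(self):
        g = random_graph_matched(58, 264, seed=1)
        assert global_efficiency(g) - g.cost > 0


# ---------------------------------------------------------------- null models

class TestNullModels:
    @given(st.integers(4, 20), st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_exact_edge_counts(self, n, data):
        m = data.draw(st.integers(0, n * (n - 1) // 2))
        assert random_graph_matched(n, m, seed=0).n_edges == m
        assert regular_lattice_matched(n, m).n_edges == m
        assert watts_strogatz_matched(n, m, 0.3, seed=0).n_edges == m

    def test_random_graph_seed_determinism_and_variability(self):
        a = random_graph_matched(58, 264, seed=5)
        b = random_graph_matched(58, 264, seed=5)
        np.testing.assert_array_equal(a.adj, b.adj)
        distinct = {random_graph_matched(20, 40, seed=s).adj.tobytes() for s in range(100)}
        assert len(distinct) > 90

    def test_random_m_out_of_range(self):
        with pytest.raises(ValueError):
            random_graph_matched(5, 11)

    def test_lattice_n6_m6_is_ring(self):
        g = regular_lattice_matched(6, 6)
        assert g.n_edges == 6
        assert np.array_equal(g.adj, nx.to_numpy_array(nx.cycle_graph(6)).astype(g.adj.dtype))

    def test_lattice_complete_when_m_max(self):
        g = regular_lattice_matched(6, 15)
        assert np.array_equal(g.adj, (1 - np.eye(6)).astype(g.adj.dtype))

    def test_lattice_more_clustered_than_random(self):
        lat_cp, _ = clustering_and_pathlength(regular_lattice_matched(58, 264))
        rnd_cp = np.mean(
            [clustering_and_pathlength(random_graph_matched(58, 264, s))[0] for s in range(20)]
        )
        assert lat_cp > rnd_cp

    def test_cost_at_58_264(self):
        assert random_graph_matched(58, 264, 0).cost == pytest.approx(0.1597, abs=5e-4)

    def test_edgelist_and_adjacency_csv_roundtrip(self, tmp_path, rng):
        g = AdjacencyGraph(random_adj(12, 0.3, rng))
        g.to_edgelist(tmp_path / "g.edges")
        back = AdjacencyGraph.from_edgelist(tmp_path / "g.edges")
        np.testing.assert_array_equal(back.adj, g.adj)
        g.to_csv(tmp_path / "g.csv")
        np.testing.assert_array_equal(AdjacencyGraph.from_csv(tmp_path / "g.csv").adj, g.adj)


# -------------------------------------------------------------- sigma, regime

class TestSigma:
    def test_watts_strogatz_graph_is_small_world(self):
        g = watts_strogatz_matched(58, 264, 0.1, seed=7)
        nulls = build_null_ensemble(58, 264, n_draws=20, seed=7)
        assert sigma_small_worldness(g, nulls) > 1

    def test_complete_graph_sigma_one(self):
        n = 20
        g = AdjacencyGraph(1 - np.eye(n))
        nulls = build_null_ensemble(n, n * (n - 1) // 2, n_draws=3, seed=0)
        assert sigma_small_worldness(g, nulls) == pytest.approx(1.0)

    def test_random_member_sigma_near_one(self):
        nulls = build_null_ensemble(58, 264, n_draws=20, seed=3)
        sigmas = [
            sigma_small_worldness(random_graph_matched(58, 264, 500 + t), nulls)
            for t in range(50)
        ]
        assert abs(np.mean(sigmas) - 1) < 0.2

    def test_mismatched_ensemble_rejected(self):
        g = watts_strogatz_matched(20, 40, 0.1, seed=0)
        with pytest.raises(ValueError):
            sigma_small_worldness(g, build_null_ensemble(20, 41, 2, 0))


class TestSmallWorldRegime:
    def _nulls(self, costs, n=30):
        npairs = n * (n - 1) // 2
        return [
            build_null_ensemble(n, int(round(c * npairs)), n_draws=5, seed=int(c * 100))
            for c in costs
        ]

    def test_curve_equal_to_random_mean_is_invalid(self):
        costs = np.array([0.2, 0.3])
        nulls = self._nulls(costs)
        eg = MetricCurve("Eglob", costs, np.array([nl.mean_eglob_random for nl in nulls]))
        el = MetricCurve("Elocal", costs, np.array([nl.mean_elocal_random for nl in nulls]))
        regime = small_world_regime(eg, el, nulls)
        assert not regime.valid

    def test_regular_lattice_curve_is_invalid(self):
        costs = np.array([0.2, 0.3])
        nulls = self._nulls(costs)
        n, npairs = 30, 30 * 29 // 2
        eg_vals, el_vals = [], []
        for c in costs:
            g = regular_lattice_matched(n, int(round(c * npairs)))
            eg_vals.append(global_efficiency(g))
            el_vals.append(local_efficiency(g))
        regime = small_world_regime(
            MetricCurve("Eglob", costs, np.array(eg_vals)),
            MetricCurve("Elocal", costs, np.array(el_vals)),
            nulls,
        )
        assert not regime.valid

    def test_ws_curves_fall_in_regime(self):
        costs = np.array([0.2, 0.3, 0.4])
        n, npairs = 30, 30 * 29 // 2
        nulls = self._nulls(costs)
        eg_vals, el_vals = [], []
        for c in costs:
            g = watts_strogatz_matched(n, int(round(c * npairs)), 0.2, seed=9)
            eg_vals.append(global_efficiency(g))
            el_vals.append(local_efficiency(g))
        regime = small_world_regime(
            MetricCurve("Eglob", costs, np.array(eg_vals)),
            MetricCurve("Elocal", costs, np.array(el_vals)),
            nulls,
        )
        assert regime.valid and regime.c_low == pytest.approx(0.2)
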