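import numpy as np
import pytest

import oracles
from conftest import (
    complete_adjacency,
    graph_from_adjacency,
    path_adjacency,
    star_adjacency,
    two_triangles_adjacency,
)
from petnet import metrics as gm


class TestClosedForms:
    def test_triangle_degree_and_strength(self, make_graph):
        g = make_graph(complete_adjacency(3))
        deg, stren = gm.degree_and_strength(g)
        assert deg == pytest.approx(2.0) and stren == pytest.approx(2.0)

    def test_star_average_degree(self, make_graph):
        g = make_graph(star_adjacency(3))
        deg, _ = gm.degree_and_strength(g)
        assert deg == pytest.approx(6 / 4)

    def test_weighted_triangle_strength(self, make_graph):
        w = np.zeros((3, 3))
        for (i, j), v in {(0, 1): 0.9, (0, 2): 0.8, (1, 2): 0.7}.items():
            w[i, j] = w[j, i] = v
        g = make_graph(complete_adjacency(3), weights=w)
        _, stren = gm.degree_and_strength(g)
        assert stren == pytest.approx(2 * 2.4 / 3)

    def test_complete_graph_path_length_one(self, make_graph):
        assert gm.characteristic_path_length(make_graph(complete_adjacency(4))) == 1.0

    def test_three_node_path_length(self, make_graph):
        assert gm.characteristic_path_length(make_graph(path_adjacency(3))) == pytest.approx(4 / 3)

    def test_disconnected_pairs_excluded(self, make_graph):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        assert gm.characteristic_path_length(make_graph(a)) == pytest.approx(1.0)

    def test_complete_graph_efficiency_one(self, make_graph):
        assert gm.global_efficiency(make_graph(complete_adjacency(5))) == pytest.approx(1.0)

    def test_edgeless_graph_efficiency_zero(self, make_graph):
        assert gm.global_efficiency(make_graph(np.zeros((4, 4)))) == 0.0

    def test_three_node_path_efficiency(self, make_graph):
        assert gm.global_efficiency(make_graph(path_adjacency(3))) == pytest.approx(5 / 6)

    def test_local_efficiency_complete(self, make_graph):
        assert gm.local_efficiency(make_graph(complete_adjacency(4))) == pytest.approx(1.0)

    def test_local_efficiency_star_zero(self, make_graph):
        assert gm.local_efficiency(make_graph(star_adjacency(4))) == 0.0

    def test_clustering_triangle_one_star_zero(self, make_graph):
        assert gm.mean_clustering(make_graph(complete_adjacency(3))) == pytest.approx(1.0)
        assert gm.mean_clustering(make_graph(star_adjacency(4))) == 0.0

    def test_two_triangles_modularity_half(self, make_graph):
        q, partition = gm.modularity(make_graph(two_triangles_adjacency()), seed=0)
        assert q == pytest.approx(0.5, abs=1e-12)
        assert len(set(partition[:3])) == 1 and len(set(partition[3:])) == 1
        assert partition[0] != partition[3]

    def test_complete_graph_modularity_zero(self, make_graph):
        q, _ = gm.modularity(make_graph(complete_adjacency(5)), seed=0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_star_assortativity_minus_one(self, make_graph):
        assert gm.assortativity(make_graph(star_adjacency(4))) == pytest.approx(-1.0)

    def test_cycle_assortativity_undefined(self, make_graph):
        a = path_adjacency(5)
        a[0, 4] = a[4, 0] = 1  # close the ring: all degrees equal
        with pytest.raises(ValueError, match="undefined"):
            gm.assortativity(make_graph(a))

    def test_star_hub_betweenness_one(self, make_graph):
        bc = gm.betweenness(make_graph(star_adjacency(3)))
        assert bc[0] == pytest.approx(1.0)
        assert np.allclose(bc[1:], 0.0)

    def test_complete_graph_betweenness_zero(self, make_graph):
        assert np.allclose(gm.betweenness(make_graph(complete_adjacency(5))), 0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial", range(25))
    def test_measures_match_brute_force(self, trial, make_graph):
        rng = np.random.default_rng(1000 + trial)
        a = oracles.random_connected_adjacency(rng)
        g = make_graph(a)
        assert gm.characteristic_path_length(g) == pytest.approx(
            oracles.path_length_oracle(a), abs=1e-10
        )
        assert gm.global_efficiency(g) == pytest.approx(
            oracles.efficiency_oracle(a), abs=1e-10
        )
        assert gm.local_efficiency(g) == pytest.approx(
            oracles.local_efficiency_oracle(a), abs=1e-10
        )
        assert gm.mean_clustering(g) == pytest.approx(
            oracles.clustering_oracle(a), abs=1e-10
        )
        assert np.allclose(gm.betweenness(g), oracles.betweenness_oracle(a), atol=1e-10)
        q, _ = gm.modularity(g, seed=trial)
        assert q == pytest.approx(oracles.max_modularity_oracle(a), abs=1e-10)
        try:
            r_oracle = oracles.assortativity_oracle(a)
        except ValueError:
            with pytest.raises(ValueError):
                gm.assortativity(g)
        else:
            assert gm.assortativity(g) == pytest.approx(r_oracle, abs=1e-10)


class TestSmallWorldness:
    def test_self_null_gives_sigma_one(self, make_graph):
        rng = np.random.default_rng(3)
        a = oracles.random_connected_adjacency(rng)
        g = make_graph(a)
        sigma = gm.small_worldness(g, n_null=5, seed=0, rewire_attempts_per_edge=0)
        assert sigma == pytest.approx(1.0)

    def test_watts_strogatz_ring_is_small_world(self, make_graph):
        import networkx as nx

        ws = nx.watts_strogatz_graph(100, 6, 0.1, seed=42)
        a = nx.to_numpy_array(ws).astype(np.int8)
        sigma = gm.small_worldness(graph_from_adjacency(a), n_null=10, seed=1)
        assert sigma > 1.0

    def test_seed_determinism(self, make_graph):
        rng = np.random.default_rng(5)
        a = oracles.random_connected_adjacency(rng)
        g = make_graph(a)
        s1 = gm.small_worldness(g, n_null=8, seed=9)
        s2 = gm.small_worldness(g, n_null=8, seed=9)
        assert s1 == s2

    def test_rewired_null_preserves_degree_sequence(self):
        from petnet.metrics import _rewire_degree_preserving

        rng = np.random.default_rng(11)
        a = oracles.random_connected_adjacency(rng)
        null, n_swapped = _rewire_degree_preserving(a, rng, 10)
        assert np.array_equal(null.sum(axis=1), a.sum(axis=1))
        assert np.array_equal(null, null.T)
        assert not np.any(np.diag(null))


class TestInvariantsAndMonotonicity:
    @pytest.mark.parametrize("trial", range(10))
    def test_efficiency_vs_path_length_inequality(self, trial, make_graph):
        """Harmonic mean of distances >= inverse arithmetic mean: for a
        connected graph E_glob >= 1/L."""
        rng = np.random.default_rng(2000 + trial)
        while True:
            a = oracles.random_connected_adjacency(rng)
            d = oracles.floyd_warshall_hops(a)
            if np.all(np.isfinite(d)):
                break
        g = make_graph(a)
        assert gm.global_efficiency(g) >= 1.0 / gm.characteristic_path_length(g) - 1e-12

    @pytest.mark.parametrize("trial", range(10))
    def test_adding_edge_monotonicity(self, trial, make_graph):
        rng = np.random.default_rng(3000 + trial)
        a = oracles.random_connected_adjacency(rng)
        absent = [(i, j) for i in range(len(a)) for j in range(i + 1, len(a)) if not a[i, j]]
        if not absent:
            return
        i, j = absent[rng.integers(len(absent))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        g_before, g_after = make_graph(a), make_graph(b)
        assert gm.global_efficiency(g_after) >= gm.global_efficiency(g_before) - 1e-12
        d_before = oracles.floyd_warshall_hops(a)
        if np.all(np.isfinite(d_before)):  # L monotone only when connectivity fixed
            assert gm.characteristic_path_length(g_after) <= (
                gm.characteristic_path_length(g_before) + 1e-12
            )

    @pytest.mark.parametrize("n", [5, 7, 9])
    def test_tree_betweenness_sum_rule(self, n, make_graph):
        """For a tree, each pair's unique path places d-1 interior nodes, so
        unnormalized betweenness sums to sum over pairs of (d - 1)."""
        import networkx as nx

        tree = nx.random_labeled_tree(n, seed=4)
        a = nx.to_numpy_array(tree).astype(np.int8)
        bc = gm.betweenness(make_graph(a))
        unnorm = bc * (n - 1) * (n - 2) / 2
        d = oracles.floyd_warshall_hops(a)
        interior_total = sum(
            d[i, j] - 1 for i in range(n) for j in range(i + 1, n)
        )
        assert unnorm.sum() == pytest.approx(interior_total)

    def test_metric_set_complete_graph_and_determinism(self, make_graph):
        g = make_graph(complete_adjacency(4))
        ms1 = gm.metric_set(g, seed=5, n_null_sigma=3)
        ms2 = gm.metric_set(g, seed=5, n_null_sigma=3)
        assert ms1.average_degree == 3.0
        assert ms1.characteristic_path_length == 1.0
        assert ms1.global_efficiency == 1.0
        assert ms1.mean_clustering == 1.0
        assert ms1.modularity == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(ms1.assortativity)  # regular graph: undefined
        d1, d2 = ms1.as_dict(), ms2.as_dict()
        for key in d1:
            np.testing.assert_array_equal(d1[key], d2[key])

    def test_metric_set_two_triangles(self, make_graph):
        ms = gm.metric_set(make_graph(two_triangles_adjacency()), seed=0, n_null_sigma=3)
        assert ms.modularity == pytest.approx(0.5, abs=1e-12)
        assert ms.mean_clustering == pytest.approx(1.0)

    def test_average_degree_identity(self, make_graph):
        rng = np.random.default_rng(6)
        a = oracles.random_connected_adjacency(rng)
        g = make_graph(a)
        deg, _ = gm.degree_and_strength(g)
        assert deg == pytest.approx(2 * g.edge_count / g.n_nodes)

    def test_modularity_edgeless_fails(self, make_graph):
        with pytest.raises(ValueError, match="edgeless"):
            gm.modularity(make_graph(np.zeros((4, 4))), seed=0)

    def test_path_length_edgeless_fails(self, make_graph):
        with pytest.raises(ValueError, match="path"):
            gm.characteristic_path_length(make_graph(np.zeros((4, 4))))
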