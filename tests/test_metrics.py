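import math

import numpy as np
import pytest

from strucnet.construct import BinaryNetwork
from strucnet.metrics import (
    characteristic_path_length,
    clustering_coefficient,
    compute_metrics,
    degree_sequence,
    global_efficiency,
    random_reference,
    small_worldness,
)
from strucnet.modularity import modularity_newman, modularity_q
from strucnet.synth import GeneratorSpec, generate_network

from conftest import network_from_edges, random_network


def floyd_warshall(adj):
    """Independent all-pairs shortest-path oracle."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def triple_loop_clustering(adj):
    """Independent triangle-counting oracle."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        k = adj[i].sum()
        if k < 2:
            continue
        tri = 0
        for j in range(n):
            for l in range(n):
                if adj[i, j] and adj[i, l] and adj[j, l]:
                    tri += 1
        out[i] = tri / (k * (k - 1))
    return out


class TestDegreesAndClustering:
    def test_regular_triangle_degrees(self, triangle):
        deg, d = degree_sequence(triangle)
        np.testing.assert_array_equal(deg, [2, 2, 2])
        assert d == 2

    def test_star_degrees(self, star5):
        deg, d = degree_sequence(star5)
        np.testing.assert_array_equal(deg, [4, 1, 1, 1, 1])
        assert d == pytest.approx(1.6)

    def test_empty_graph_degrees(self):
        deg, d = degree_sequence(network_from_edges(3, []))
        np.testing.assert_array_equal(deg, [0, 0, 0])
        assert d == 0

    def test_triangle_fully_clustered(self, triangle):
        _, c = clustering_coefficient(triangle)
        assert c == 1.0

    def test_star_has_no_triangles(self, star5):
        _, c = clustering_coefficient(star5)
        assert c == 0.0

    def test_k4_minus_edge_by_hand(self, k4_minus_edge):
        per_node, c = clustering_coefficient(k4_minus_edge)
        np.testing.assert_allclose(sorted(per_node), [2 / 3, 2 / 3, 1, 1])
        assert c == pytest.approx(5 / 6)


class TestPathsAndEfficiency:
    def test_complete_graph_paths(self, k5):
        i_g, frac = characteristic_path_length(k5)
        assert (i_g, frac) == (1.0, 0.0)
        assert global_efficiency(k5) == 1.0

    def test_path_graph_by_hand(self, path4):
        i_g, frac = characteristic_path_length(path4)
        assert i_g == pytest.approx(10 / 6)
        assert frac == 0.0

    def test_disconnected_pairs_excluded_and_reported(self, two_disjoint_edges):
        i_g, frac = characteristic_path_length(two_disjoint_edges)
        assert i_g == 1.0
        assert frac == pytest.approx(4 / 6)
        assert global_efficiency(two_disjoint_edges) == pytest.approx(2 / 6)

    def test_efficiency_path3_by_hand(self):
        net = network_from_edges(3, [(0, 1), (1, 2)])
        assert global_efficiency(net) == pytest.approx((1 + 1 + 0.5) / 3)

    def test_edgeless_graph_has_no_path_length(self):
        with pytest.raises(ValueError, match="no edges"):
            characteristic_path_length(network_from_edges(3, []))
        assert global_efficiency(network_from_edges(3, [])) == 0.0

    def test_adding_an_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            net = random_network(rng, 4, 10)
            e = global_efficiency(net)
            free = np.argwhere(np.triu(net.adjacency == 0, 1))
            if len(free) == 0:
                continue
            i, j = free[rng.integers(len(free))]
            adj = net.adjacency.copy()
            adj[i, j] = adj[j, i] = 1
            assert global_efficiency(
                BinaryNetwork(adj, net.node_labels)
            ) >= e - 1e-12


class TestRandomReference:
    def test_closed_form_values(self):
        assert random_reference(100, 10) == (0.1, 2.0)

    def test_natural_log_convention(self):
        c_r, i_r = random_reference(68, math.e)
        assert i_r == pytest.approx(math.log(68))
        assert c_r == pytest.approx(math.e / 68)

    @pytest.mark.parametrize("d", [1.0, 0.5, 0.0])
    def test_degree_at_most_one_is_out_of_domain(self, d):
        with pytest.raises(ValueError):
            random_reference(100, d)


class TestSmallWorldness:
    def test_sigma_is_exactly_gamma_over_lambda(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            net = random_network(rng, 8, 14, p=0.5)
            if net.degrees().mean() <= 1 or net.n_edges == 0:
                continue
            sw = small_worldness(net)
            assert sw["sigma"] == sw["gamma"] / sw["lambda_"]

    def test_equal_observed_and_reference_values_give_sigma_one_exactly(self):
        # the ratio identity: identical numerators and denominators
        # cancel exactly in IEEE arithmetic
        rng = np.random.default_rng(3)
        net = random_network(rng, 10, 10, p=0.6)
        sw = small_worldness(net)
        gamma = sw["C_G"] / sw["C_G"]
        lam = sw["I_G"] / sw["I_G"]
        assert gamma / lam == 1.0

    def test_watts_strogatz_ring_is_small_world(self):
        for seed in range(5):
            net = generate_network(
                GeneratorSpec(n_nodes=500, model="watts_strogatz",
                              ws_neighbors=10, ws_rewire=0.1, seed=seed)
            )
            assert small_worldness(net)["sigma"] > 1

    def test_dense_er_sigma_near_but_below_one(self):
        # frozen band from direct simulation: the analytic reference
        # slightly understates path length at this density
        for seed in range(5):
            net = generate_network(
                GeneratorSpec(n_nodes=200, model="er", d=0.2 * 199, seed=seed)
            )
            assert 0.75 <= small_worldness(net)["sigma"] <= 0.9


class TestModularity:
    def test_single_community_q_is_zero(self, triangle):
        assert modularity_q(triangle.adjacency, np.zeros(3)) == pytest.approx(0)

    def test_two_triangles_split_matches_exhaustive_maximum(self):
        net = network_from_edges(
            6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
        )
        q, mem = modularity_newman(net)
        assert q == pytest.approx(0.3571428571428571)
        assert len(set(mem[:3])) == 1 and len(set(mem[3:])) == 1
        assert mem[0] != mem[3]

    def test_planted_four_blocks_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        net = generate_network(
            GeneratorSpec(n_nodes=80, model="planted_modular", n_modules=4,
                          p_in=0.3, p_out=0.01, seed=1)
        )
        _, mem = modularity_newman(net)
        assert adjusted_rand_score(np.arange(80) % 4, mem) >= 0.9

    def test_no_edges_is_an_error(self):
        with pytest.raises(ValueError, match="no edges"):
            modularity_newman(network_from_edges(4, []))

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        net = random_network(rng, 20, 20, p=0.2)
        if net.n_edges == 0:
            pytest.skip("empty draw")
        q1, m1 = modularity_newman(net)
        q2, m2 = modularity_newman(net)
        assert q1 == q2
        np.testing.assert_array_equal(m1, m2)


class TestInvariances:
    def test_metrics_invariant_under_node_relabeling(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_network(rng, 6, 12, p=0.5)
            if net.degrees().mean() <= 1:
                continue
            perm = rng.permutation(net.n_nodes)
            permuted = BinaryNetwork(
                net.adjacency[np.ix_(perm, perm)],
                [net.node_labels[i] for i in perm],
            )
            a = compute_metrics(net)
            b = compute_metrics(permuted)
            for f in ("d", "C_G", "I_G", "E_glob", "sigma", "Q",
                      "frac_disconnected"):
                assert getattr(a, f) == pytest.approx(
                    getattr(b, f), abs=1e-12
                ), f

    def test_paths_efficiency_match_floyd_warshall_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            net = random_network(rng, 4, 12)
            if net.n_edges == 0:
                continue
            d = floyd_warshall(net.adjacency.astype(float))
            off = ~np.eye(net.n_nodes, dtype=bool)
            finite = np.isfinite(d) & off
            i_g, frac = characteristic_path_length(net)
            assert i_g == pytest.approx(d[finite].mean(), abs=0)
            inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
            assert global_efficiency(net) == pytest.approx(
                inv[off].sum() / off.sum(), abs=1e-15
            )

    def test_clustering_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            net = random_network(rng, 4, 12)
            per_node, avg = clustering_coefficient(net)
            oracle = triple_loop_clustering(net.adjacency)
            np.testing.assert_allclose(per_node, oracle, atol=1e-12)
            assert avg == pytest.approx(oracle.mean(), abs=1e-12)
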