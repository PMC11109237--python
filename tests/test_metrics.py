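"""Weighted graph metrics against brute-force oracles and closed forms."""

import networkx as nx
import numpy as np
import pytest

from cognet.metrics import (
    clustering,
    global_efficiency,
    local_efficiency,
    metric_vector,
    modularity,
    modularity_q,
    shortest_distances,
    strength,
    summarize,
)
from cognet.tmfg import WeightedNetwork, tmfg

from oracles import (
    brute_distances,
    brute_efficiency,
    brute_local_efficiency,
    brute_onnela_clustering,
    random_symmetric_weights,
)


def star(weight=0.5, leaves=3):
    w = np.zeros((leaves + 1, leaves + 1))
    w[0, 1:] = w[1:, 0] = weight
    return w


def triangle(w12=1.0, w13=1.0, w23=1.0):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w12
    w[0, 2] = w[2, 0] = w13
    w[1, 2] = w[2, 1] = w23
    return w


class TestStrength:
    def test_star(self):
        s = strength(star())
        np.testing.assert_allclose(s, [1.5, 0.5, 0.5, 0.5])

    def test_handshake_identity(self, rng):
        w = random_symmetric_weights(rng, 10)
        assert strength(w).sum() == pytest.approx(2 * np.triu(w, 1).sum(), abs=1e-9)


class TestDistances:
    def test_two_nodes(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(shortest_distances(w), [[0, 2], [2, 0]])

    def test_relaxation_through_strong_edges(self):
        # weak direct edge (length 10) loses to the two-hop strong path (2)
        d = shortest_distances(triangle(1.0, 1.0, 0.1))
        assert d[1, 2] == pytest.approx(2.0)

    def test_disconnected_pair_infinite(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        d = shortest_distances(w)
        assert np.isinf(d[0, 2])

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            w = random_symmetric_weights(rng, 8)
            w[w < 0.3] = 0.0  # sparsify so paths matter
            np.testing.assert_allclose(
                shortest_distances(w), brute_distances(w), atol=1e-9
            )


class TestEfficiency:
    def test_two_nodes(self):
        w = np.array([[0.0, 0.5], [0.5, 0.0]])
        assert global_efficiency(w) == pytest.approx(0.5)

    def test_uniform_complete_graph_is_one(self):
        for n in (4, 6):
            w = np.ones((n, n)) - np.eye(n)
            assert global_efficiency(w) == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            w = random_symmetric_weights(rng, 7)
            w[w < 0.3] = 0.0
            assert global_efficiency(w) == pytest.approx(brute_efficiency(w), abs=1e-9)


class TestClustering:
    def test_uniform_triangle_is_one(self):
        np.testing.assert_allclose(clustering(triangle(0.7, 0.7, 0.7)), 1.0)

    def test_star_is_zero(self):
        np.testing.assert_allclose(clustering(star()), 0.0)

    def test_mixed_weights_match_triple_loop_oracle(self, rng):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.9
        w[0, 2] = w[2, 0] = 0.4
        w[1, 2] = w[2, 1] = 0.6
        w[0, 3] = w[3, 0] = 0.2
        np.testing.assert_allclose(
            clustering(w), brute_onnela_clustering(w), atol=1e-12
        )

    def test_matches_oracle_and_networkx(self, rng):
        for _ in range(5):
            w = random_symmetric_weights(rng, 8)
            w[w < 0.3] = 0.0
            mine = clustering(w)
            np.testing.assert_allclose(mine, brute_onnela_clustering(w), atol=1e-9)
            g = nx.from_numpy_array(w)
            g.remove_edges_from([(u, v) for u, v, d in g.edges(data=True) if d["weight"] == 0])
            nx_c = nx.clustering(g, weight="weight")
            np.testing.assert_allclose(mine, [nx_c[i] for i in range(8)], atol=1e-9)


class TestLocalEfficiency:
    def test_complete_triangle_neighborhood(self):
        # node 0's neighbors {1,2,3} form a uniform weight-1 triangle
        w = np.ones((4, 4)) - np.eye(4)
        assert local_efficiency(w)[0] == pytest.approx(1.0)

    def test_single_neighbor_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        np.testing.assert_allclose(local_efficiency(w), 0.0)

    def test_matches_compositional_oracle(self, rng):
        for _ in range(5):
            w = random_symmetric_weights(rng, 6)
            w[w < 0.4] = 0.0
            np.testing.assert_allclose(
                local_efficiency(w), brute_local_efficiency(w), atol=1e-9
            )


class TestModularity:
    def two_triangles(self):
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            w[i, j] = w[j, i] = 1.0
        w[2, 3] = w[3, 2] = 0.01
        return w

    def test_two_triangles_partitioned(self):
        w = self.two_triangles()
        labels, q = modularity(w, n_restarts=20, seed=0)
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]
        assert labels[0] != labels[3]
        # direct formula evaluation on that partition
        assert q == pytest.approx(modularity_q(w, labels), abs=1e-12)
        # hand evaluation via the standard e_c - a_c^2 form
        m = np.triu(w, 1).sum()
        s = w.sum(axis=0)
        hand = 0.0
        for members in ([0, 1, 2], [3, 4, 5]):
            within = sum(
                w[i, j] for i in members for j in members if i < j
            )
            a_c = s[members].sum() / (2 * m)
            hand += within / m - a_c**2
        assert q == pytest.approx(hand, abs=1e-12)

    def test_single_community_q_is_zero_on_complete_graph(self):
        w = 0.5 * (np.ones((5, 5)) - np.eye(5))
        assert modularity_q(w, np.zeros(5, dtype=int)) == pytest.approx(0.0, abs=1e-12)

    def test_optimizer_dominates_trivial_partition(self, rng):
        w = random_symmetric_weights(rng, 8)
        _, q = modularity(w, n_restarts=10, seed=1)
        assert q >= modularity_q(w, np.zeros(8, dtype=int)) - 1e-12

    def test_q_bounds(self, rng):
        for _ in range(10):
            w = random_symmetric_weights(rng, 7)
            _, q = modularity(w, n_restarts=5, seed=2)
            assert -0.5 <= q <= 1.0

    def test_matches_networkx_quality(self, rng):
        w = random_symmetric_weights(rng, 8)
        labels, q = modularity(w, n_restarts=10, seed=3)
        g = nx.from_numpy_array(w)
        communities = [set(np.where(labels == c)[0]) for c in np.unique(labels)]
        nx_q = nx.community.modularity(g, communities, weight="weight")
        assert q == pytest.approx(nx_q, abs=1e-12)


class TestScaleCovariance:
    def test_scaling_weights(self, rng):
        w = random_symmetric_weights(rng, 8)
        lam = 3.7
        np.testing.assert_allclose(strength(lam * w), lam * strength(w), atol=1e-9)
        assert global_efficiency(lam * w) == pytest.approx(
            lam * global_efficiency(w), abs=1e-9
        )
        np.testing.assert_allclose(clustering(lam * w), clustering(w), atol=1e-12)
        _, q1 = modularity(w, n_restarts=5, seed=4)
        _, q2 = modularity(lam * w, n_restarts=5, seed=4)
        assert q1 == pytest.approx(q2, abs=1e-9)


class TestSummarize:
    def test_trivial_two_node_network(self):
        net = WeightedNetwork(("a", "b", "c", "d"), np.zeros((4, 4)))
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        two = WeightedNetwork(("a", "b"), w)
        node_table, glob = summarize(two, n_restarts=5)
        assert glob.global_strength == pytest.approx(1.0)
        assert glob.global_efficiency == pytest.approx(0.5)
        assert glob.global_clustering == pytest.approx(0.0)

    def test_tmfg_output_shapes_and_finiteness(self, rng):
        net = tmfg(random_symmetric_weights(rng, 10))
        node_table, glob = summarize(net, n_restarts=10)
        assert node_table.shape == (10, 3)
        assert np.isfinite(node_table.to_numpy()).all()
        vals = glob.as_dict()
        assert len(vals) == 4
        assert all(np.isfinite(v) for v in vals.values())
        assert glob.global_strength == pytest.approx(
            node_table["strength"].sum(), abs=1e-9
        )

    def test_metric_vector_consistent_with_summarize(self, rng):
        net = tmfg(random_symmetric_weights(rng, 8))
        node_table, glob = summarize(net, n_restarts=10, seed=5)
        mv = metric_vector(net.weights, net.nodes, n_restarts=10, seed=5)
        for key, value in glob.as_dict().items():
            assert mv[key] == pytest.approx(value, abs=1e-12)
        for node in net.nodes:
            assert mv[f"strength[{node}]"] == pytest.approx(
                node_table.loc[node, "strength"], abs=1e-12
            )
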