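"""Centrality measures, distance transform, shortest paths, sign split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beliefnet import (
    WeightedNetwork,
    betweenness,
    closeness,
    shortest_paths_to,
    split_by_sign,
    strength,
    to_distance,
)
from conftest import net_from_edges
from oracles import (
    brute_betweenness,
    brute_closeness,
    brute_shortest_path,
    random_signed_network,
)


class TestStrength:
    def test_sums_absolute_incident_weights(self):
        net = net_from_edges("ABC", [("A", "B", 0.5), ("B", "C", -0.3)])
        s = strength(net)
        assert s["B"] == pytest.approx(0.8)
        assert s["A"] == pytest.approx(0.5)

    def test_isolated_node_has_zero_strength(self):
        net = net_from_edges("ABC", [("A", "B", 0.4)])
        assert strength(net)["C"] == 0.0

    def test_matches_row_sum_oracle_on_random_networks(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            w = random_signed_network(rng, 10)
            net = WeightedNetwork(w, [f"n{i}" for i in range(10)])
            assert np.allclose(strength(net).to_numpy(), np.abs(w).sum(axis=1))


class TestDistanceTransform:
    def test_reciprocal_of_absolute_weight(self):
        net = net_from_edges("ABC", [("A", "B", 0.25), ("B", "C", -0.25)])
        g = to_distance(net)
        assert g["A"]["B"]["length"] == pytest.approx(4.0)
        assert g["B"]["C"]["length"] == pytest.approx(4.0)

    def test_absent_edges_have_no_distance_entry(self):
        net = net_from_edges("ABC", [("A", "B", 0.5)])
        g = to_distance(net)
        assert not g.has_edge("A", "C")

    def test_inverse_log_transform_option(self):
        net = net_from_edges("AB", [("A", "B", 0.5)])
        g = to_distance(net, transform="inverse_log")
        assert g["A"]["B"]["length"] == pytest.approx(-np.log(0.5))


class TestShortestPaths:
    def test_three_node_path_distances_and_route(self, path3_net):
        res = shortest_paths_to(path3_net, "C")
        assert res.distance == pytest.approx({"C": 0.0, "B": 2.0, "A": 4.0})
        assert res.path["A"] == ["A", "B", "C"]

    def test_indirect_route_beats_weak_direct_edge(self):
        net = net_from_edges(
            "ABC", [("A", "C", 0.1), ("A", "B", 0.5), ("B", "C", 0.5)]
        )
        res = shortest_paths_to(net, "C")
        assert res.distance["A"] == pytest.approx(4.0)  # via B, not the 10.0 direct hop
        assert res.path["A"] == ["A", "B", "C"]

    def test_focal_node_is_at_distance_zero(self, path3_net):
        res = shortest_paths_to(path3_net, "B")
        assert res.distance["B"] == 0.0
        assert res.path["B"] == ["B"]

    def test_unreachable_nodes_get_infinite_distance_and_empty_path(self):
        net = net_from_edges("ABCD", [("A", "B", 0.5), ("C", "D", 0.5)])
        res = shortest_paths_to(net, "A")
        assert np.isinf(res.distance["C"])
        assert res.path["C"] == []

    def test_unknown_focal_label_rejected(self, path3_net):
        with pytest.raises(KeyError):
            shortest_paths_to(path3_net, "Z")

    def test_matches_exhaustive_oracle_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = int(rng.integers(4, 9))
            w = random_signed_network(rng, p, density=0.45)
            labels = [f"n{i}" for i in range(p)]
            net = WeightedNetwork(w, labels)
            res = shortest_paths_to(net, labels[0])
            for j in range(p):
                d_expect, path_expect = brute_shortest_path(w, j, 0)
                assert res.distance[labels[j]] == pytest.approx(d_expect)
                assert res.path[labels[j]] == [labels[k] for k in path_expect]

    def test_reported_path_length_equals_distance(self):
        rng = np.random.default_rng(2)
        w = random_signed_network(rng, 8, density=0.5)
        net = WeightedNetwork(w, list("ABCDEFGH"))
        res = shortest_paths_to(net, "A")
        for v, path in res.path.items():
            if not path:
                continue
            total = sum(
                1.0 / abs(w[net.index_of(a), net.index_of(b)])
                for a, b in zip(path, path[1:])
            )
            assert total == pytest.approx(res.distance[v], abs=1e-9)


class TestCloseness:
    def test_three_node_path_hand_values(self, path3_net):
        c = closeness(path3_net)
        assert c["B"] == pytest.approx(0.25)
        assert c["A"] == pytest.approx(1.0 / 6.0)

    def test_isolated_node_scores_zero(self):
        net = net_from_edges("ABC", [("A", "B", 0.5)])
        assert closeness(net)["C"] == 0.0

    def test_matches_dijkstra_oracle_on_random_connected_network(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            w = random_signed_network(rng, 8, density=0.6)
            net = WeightedNetwork(w, [f"n{i}" for i in range(8)])
            expected = brute_closeness(w)
            got = closeness(net).to_numpy()
            assert np.allclose(got, expected)


class TestBetweenness:
    def test_star_center_counts_leaf_pairs(self):
        edges = [("C", leaf, 0.5) for leaf in "ABDE"]
        net = net_from_edges("ABCDE", edges)
        b = betweenness(net)
        assert b["C"] == pytest.approx(6.0)  # C(4, 2) leaf pairs
        assert b["A"] == 0.0

    def test_path_middle_node(self, path3_net):
        b = betweenness(path3_net)
        assert b["B"] == pytest.approx(1.0)
        assert b["A"] == b["C"] == 0.0

    def test_matches_exhaustive_oracle_with_tie_credit(self):
        rng = np.random.default_rng(4)
        for _ in range(15):
            p = int(rng.integers(4, 8))
            w = random_signed_network(rng, p, density=0.5)
            net = WeightedNetwork(w, [f"n{i}" for i in range(p)])
            assert np.allclose(
                betweenness(net).to_numpy(), brute_betweenness(w), atol=1e-9
            )


class TestSignSplit:
    def test_all_positive_network_gives_empty_negative_half(self):
        net = net_from_edges("ABC", [("A", "B", 0.4), ("B", "C", 0.2)])
        pos, neg = split_by_sign(net)
        assert pos.n_edges == 2
        assert neg.n_edges == 0

    def test_partition_keeps_magnitudes(self):
        net = net_from_edges("ABC", [("A", "B", 0.4), ("B", "C", -0.2)])
        pos, neg = split_by_sign(net)
        assert pos.weights[0, 1] == pytest.approx(0.4)
        assert neg.weights[1, 2] == pytest.approx(0.2)

    def test_node_unreachable_in_one_sign_reports_missing_path(self):
        # mirrors the "-" entries of the per-sign shortest-path table:
        # a node connected only through positive edges has no route to
        # the focal node inside the negative subnetwork
        net = net_from_edges(
            "ABCD", [("A", "B", 0.5), ("B", "C", -0.4), ("C", "D", 0.3)]
        )
        _, neg = split_by_sign(net)
        res = shortest_paths_to(neg, "B")
        assert np.isinf(res.distance["D"])
        assert res.distance["C"] == pytest.approx(1 / 0.4)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_edge_partition_is_conserved(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(3, 10))
        w = random_signed_network(rng, p, density=0.5)
        net = WeightedNetwork(w, [f"n{i}" for i in range(p)])
        pos, neg = split_by_sign(net)
        assert pos.n_edges + neg.n_edges == net.n_edges
        overlap = (pos.weights != 0) & (neg.weights != 0)
        assert not overlap.any()

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_split_never_shortens_paths(self, seed):
        rng = np.random.default_rng(seed)
        w = random_signed_network(rng, 7, density=0.5)
        net = WeightedNetwork(w, [f"n{i}" for i in range(7)])
        full = shortest_paths_to(net, "n0")
        for sub in split_by_sign(net):
            part = shortest_paths_to(sub, "n0")
            for v in part.distance:
                assert part.distance[v] >= full.distance[v] - 1e-9


class TestRelabeling:
    def test_centralities_permute_with_node_order(self):
        rng = np.random.default_rng(5)
        w = random_signed_network(rng, 8, density=0.5)
        labels = [f"n{i}" for i in range(8)]
        net = WeightedNetwork(w, labels)
        perm = rng.permutation(8)
        net_p = WeightedNetwork(w[np.ix_(perm, perm)], [labels[i] for i in perm])
        for fn in (strength, closeness, betweenness):
            a = fn(net)
            b = fn(net_p)
            for lab in labels:
                assert a[lab] == pytest.approx(b[lab], abs=1e-9)
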