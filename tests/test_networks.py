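"""Network construction and the five moderating network parameters."""

import networkx as nx
import numpy as np
import pytest
from _oracles import (
    betweenness_oracle,
    clustering_oracle,
    closeness_oracle,
    eigen_oracle,
    gini_oracle,
)
from conftest import nominations_frame

from peermod.networks import (
    YearNetwork,
    betweenness_centrality,
    build_network,
    closeness_centrality,
    eigenvector_centrality,
    gini_coefficient,
    gini_degree,
    local_clustering,
)


def net_from_graph(G) -> YearNetwork:
    return YearNetwork("T", 0, nx.DiGraph(G), nx.Graph(G), "union")


class TestBuildNetwork:
    def test_union_keeps_one_sided_nominations(self):
        net = build_network(nominations_frame([("A", "B")]), ["A", "B"], 0, "union")
        assert net.undirected.has_edge("A", "B")
        assert net.directed.has_edge("A", "B") and not net.directed.has_edge("B", "A")

    def test_intersection_requires_reciprocity(self):
        net = build_network(
            nominations_frame([("A", "B")]), ["A", "B"], 0, "intersection"
        )
        assert not net.undirected.has_edge("A", "B")
        net2 = build_network(
            nominations_frame([("A", "B"), ("B", "A")]), ["A", "B"], 0, "intersection"
        )
        assert net2.undirected.has_edge("A", "B")

    def test_mutual_pairs_identical_under_both_rules(self):
        edges = [("A", "B"), ("B", "A"), ("C", "D"), ("D", "C"), ("E", "F"), ("F", "E")]
        roster = list("ABCDEF")
        for rule in ("union", "intersection"):
            net = build_network(nominations_frame(edges), roster, 0, rule)
            assert net.undirected.number_of_edges() == 3

    def test_off_roster_and_self_nominations_dropped(self, caplog):
        edges = [("A", "B"), ("A", "A"), ("A", "Z")]
        with caplog.at_level("WARNING"):
            net = build_network(nominations_frame(edges), ["A", "B"], 0, "union")
        assert net.undirected.number_of_edges() == 1
        assert "dropped" in caplog.text

    def test_isolates_stay_on_roster(self):
        net = build_network(nominations_frame([("A", "B")]), ["A", "B", "C"], 0)
        assert "C" in net.undirected
        assert net.undirected.degree("C") == 0


class TestClustering:
    def test_triangle_scores_ten(self):
        net = net_from_graph(nx.complete_graph(3))
        assert local_clustering(net, 0) == pytest.approx(10.0)

    def test_star_center_scores_zero(self):
        net = net_from_graph(nx.star_graph(3))
        assert local_clustering(net, 0) == 0.0

    def test_k4_minus_edge(self):
        G = nx.complete_graph(4)
        G.remove_edge(2, 3)
        net = net_from_graph(G)
        # node 0 sees 3 neighbour pairs, 2 closed
        assert local_clustering(net, 0) == pytest.approx(10 * 2 / 3)

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            local_clustering(net_from_graph(nx.path_graph(3)), 99)


class TestEigenvector:
    def test_k3_symmetric_unit_norm(self):
        scores = eigenvector_centrality(net_from_graph(nx.complete_graph(3)))
        for v in scores.values():
            assert v == pytest.approx(10 / np.sqrt(3), abs=1e-9)

    def test_p3_center_to_end_ratio_sqrt2(self):
        scores = eigenvector_centrality(net_from_graph(nx.path_graph(3)))
        assert scores[1] / scores[0] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_star_graph_converges_despite_bipartite_spectrum(self):
        scores = eigenvector_centrality(net_from_graph(nx.star_graph(4)))
        lam, _, vec = eigen_oracle(nx.to_numpy_array(nx.star_graph(4)))
        np.testing.assert_allclose(
            sorted(scores.values()), sorted(vec * 10), atol=1e-8
        )

    def test_two_disjoint_k2_spread_over_tied_eigenspace(self):
        G = nx.Graph([(0, 1), (2, 3)])
        scores = eigenvector_centrality(net_from_graph(G))
        # tied leading eigenvalue across components: uniform start spreads
        for v in scores.values():
            assert v == pytest.approx(5.0, abs=1e-8)

    def test_edgeless_graph_scores_zero(self):
        G = nx.empty_graph(4)
        scores = eigenvector_centrality(net_from_graph(G))
        assert all(v == 0.0 for v in scores.values())
        assert eigenvector_centrality(net_from_graph(nx.empty_graph(0))) == {}


class TestCloseness:
    def test_p3_center_and_endpoint(self):
        net = net_from_graph(nx.path_graph(3))
        scores = closeness_centrality(net)
        assert scores[1] == pytest.approx(10.0)
        assert scores[0] == pytest.approx(10 * 2 / 3)

    def test_isolate_scores_zero(self):
        G = nx.path_graph(3)
        G.add_node(99)
        assert closeness_centrality(net_from_graph(G))[99] == 0.0

    def test_component_adjustment_on_disconnected_graph(self):
        G = nx.Graph([(0, 1), (2, 3), (3, 4)])
        scores = closeness_centrality(net_from_graph(G))
        for v in G:
            assert scores[v] == pytest.approx(closeness_oracle(G, v), abs=1e-10)


class TestBetweenness:
    def test_p3_center_is_sole_broker(self):
        scores = betweenness_centrality(net_from_graph(nx.path_graph(3)))
        assert scores[1] == pytest.approx(10.0)
        assert scores[0] == 0.0

    def test_complete_graph_all_zero(self):
        scores = betweenness_centrality(net_from_graph(nx.complete_graph(4)))
        assert all(v == 0.0 for v in scores.values())

    def test_bowtie_articulation_node_matches_path_enumeration(self):
        G = nx.Graph([(0, 1), (1, 2), (0, 2), (2, 3), (2, 4), (3, 4)])
        scores = betweenness_centrality(net_from_graph(G))
        oracle = betweenness_oracle(G)
        for v in G:
            assert scores[v] == pytest.approx(oracle[v], abs=1e-10)


class TestGini:
    def test_regular_graph_scores_zero(self):
        assert gini_degree(net_from_graph(nx.cycle_graph(6))) == 0.0

    def test_reference_degree_sequence(self):
        assert gini_coefficient([1, 1, 2, 4]) == pytest.approx(0.3125)
        assert gini_coefficient([1, 1, 2, 4]) == pytest.approx(
            gini_oracle([1, 1, 2, 4])
        )

    def test_single_nonzero_value_approaches_limit(self):
        for n in (4, 10, 50):
            seq = [5.0] + [0.0] * (n - 1)
            assert gini_coefficient(seq) == pytest.approx((n - 1) / n)

    def test_invariant_under_disjoint_duplication(self):
        G = nx.Graph([(0, 1), (1, 2), (2, 3), (1, 3)])
        doubled = nx.disjoint_union(G, G)
        assert gini_degree(net_from_graph(G)) == pytest.approx(
            gini_degree(net_from_graph(doubled))
        )

    def test_all_zero_degrees_logged_as_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert gini_degree(net_from_graph(nx.empty_graph(3))) == 0.0
        assert "Gini" in caplog.text


class TestPermutationInvariance:
    def test_relabelling_permutes_all_metrics(self):
        rng = np.random.default_rng(0)
        G = nx.gnp_random_graph(12, 0.3, seed=3)
        perm = dict(zip(G.nodes, rng.permutation(list(G.nodes))))
        H = nx.relabel_nodes(G, perm)
        net_g, net_h = net_from_graph(G), net_from_graph(H)
        for func in (eigenvector_centrality, closeness_centrality, betweenness_centrality):
            sg, sh = func(net_g), func(net_h)
            for v in G:
                assert sg[v] == pytest.approx(sh[perm[v]], abs=1e-8)
        for v in G:
            assert local_clustering(net_g, v) == pytest.approx(
                local_clustering(net_h, perm[v])
            )
        assert gini_degree(net_g) == pytest.approx(gini_degree(net_h))


def test_spot_check_random_graphs_against_oracles():
    """All four node metrics agree with brute force on random small graphs."""
    rng = np.random.default_rng(42)
    for trial in range(20):
        n = int(rng.integers(3, 8))
        G = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(1e6)))
        net = net_from_graph(G)
        A = nx.to_numpy_array(G, nodelist=list(G.nodes))
        lam, gap, vec = eigen_oracle(A)
        scores = eigenvector_centrality(net)
        got = np.array([scores[v] for v in G.nodes])
        if gap > 1e-6 and lam > 0:
            np.testing.assert_allclose(got, vec * 10, atol=1e-8)
        clo = closeness_centrality(net)
        bet = betweenness_centrality(net)
        oracle_bet = betweenness_oracle(G)
        for v in G:
            assert local_clustering(net, v) == pytest.approx(
                clustering_oracle(G, v), abs=1e-10
            )
            assert clo[v] == pytest.approx(closeness_oracle(G, v), abs=1e-10)
            assert bet[v] == pytest.approx(oracle_bet[v], abs=1e-8)
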