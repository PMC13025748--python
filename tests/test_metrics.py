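"""Topology and centrality metrics against closed forms and exhaustive oracles."""

import math

import networkx as nx
import numpy as np
import pytest

from culinet.errors import UndefinedMetricError
from culinet.metrics import (
    Partition,
    avg_clustering,
    betweenness,
    density,
    eigenvector_centrality,
    louvain_modularity,
    metrics_report,
    modularity,
    weighted_degree,
)
from culinet.networks import CooccurrenceNetwork, build_ingredient_network

from conftest import (
    brute_force_avg_clustering,
    brute_force_betweenness,
    mk_recipe,
    random_connected_graph,
)


def net_from_graph(g, level="ingredient"):
    return CooccurrenceNetwork(graph=g, level=level)


def path_net():
    g = nx.Graph()
    g.add_weighted_edges_from([("A", "B", 1), ("B", "C", 1)])
    return net_from_graph(g)


class TestDensity:
    def test_complete_graph(self):
        g = nx.complete_graph(14)
        nx.set_edge_attributes(g, 1, "weight")
        assert density(net_from_graph(g)) == 1.0

    def test_path(self):
        assert density(path_net()) == pytest.approx(2 * 2 / (3 * 2))

    def test_undefined_below_two_nodes(self):
        g = nx.Graph()
        g.add_node("A")
        with pytest.raises(UndefinedMetricError):
            density(net_from_graph(g))


class TestWeightedDegree:
    def test_star_center_share(self):
        k = 6
        g = nx.star_graph(k)
        nx.set_edge_attributes(g, 1, "weight")
        df = weighted_degree(net_from_graph(g))
        assert df.loc[0, "weighted_degree"] == k
        assert df.loc[0, "share"] == pytest.approx(50.0)

    def test_single_weighted_edge(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=7)
        df = weighted_degree(net_from_graph(g))
        assert df["weighted_degree"].tolist() == [7, 7]
        assert df["share"].tolist() == [50.0, 50.0]

    def test_shares_sum_to_100(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            df = weighted_degree(net_from_graph(random_connected_graph(rng)))
            assert df["share"].sum() == pytest.approx(100.0, abs=1e-9)


class TestBetweenness:
    def test_path_middle(self):
        bc = betweenness(path_net())
        assert bc == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_complete_graph_zero(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1, "weight")
        assert set(betweenness(net_from_graph(g)).values()) == {0.0}

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            g = random_connected_graph(rng)
            got = betweenness(net_from_graph(g))
            want = brute_force_betweenness(g)
            for v in g:
                assert got[v] == pytest.approx(want[v], abs=1e-12)


class TestEigenvector:
    def test_complete_graph_uniform(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1, "weight")
        ev = eigenvector_centrality(net_from_graph(g))
        assert max(ev.values()) == pytest.approx(min(ev.values()))
        assert sum(v * v for v in ev.values()) == pytest.approx(1.0)

    def test_two_node_weight_independent(self):
        g = nx.Graph()
        g.add_edge("A", "B", weight=9)
        ev = eigenvector_centrality(net_from_graph(g))
        assert ev["A"] == pytest.approx(ev["B"])

    def test_matches_dense_eigensolver(self):
        rng = np.random.default_rng(23)
        g = random_connected_graph(rng)
        nodes = sorted(g)
        a = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        vals, vecs = np.linalg.eigh(a)
        principal = np.abs(vecs[:, np.argmax(vals)])
        principal /= np.linalg.norm(principal)
        ev = eigenvector_centrality(net_from_graph(g))
        for i, v in enumerate(nodes):
            assert ev[v] == pytest.approx(principal[i], abs=1e-8)

    def test_offcomponent_nodes_zero(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 1), ("B", "C", 1)])
        g.add_edge("D", "E", weight=1)
        ev = eigenvector_centrality(net_from_graph(g))
        assert ev["D"] == ev["E"] == 0.0

    def test_max_normalization(self):
        g = nx.Graph()
        g.add_weighted_edges_from([("A", "B", 2), ("B", "C", 1)])
        ev = eigenvector_centrality(net_from_graph(g), norm="max")
        assert max(ev.values()) == pytest.approx(1.0)


class TestClustering:
    def test_triangle(self):
        net = build_ingredient_network([mk_recipe("r", "ABC")])
        assert avg_clustering(net) == 1.0

    def test_star(self):
        g = nx.star_graph(5)
        nx.set_edge_attributes(g, 1, "weight")
        assert avg_clustering(net_from_graph(g)) == 0.0

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            g = random_connected_graph(rng)
            assert avg_clustering(net_from_graph(g)) == pytest.approx(
                brute_force_avg_clustering(g), abs=1e-12
            )


class TestLouvain:
    def two_triangles(self):
        return build_ingredient_network(
            [mk_recipe("r1", "ABC"), mk_recipe("r2", "DEF")]
        )

    def test_two_disjoint_triangles(self):
        part, q = louvain_modularity(self.two_triangles(), seed=0)
        assert q == pytest.approx(0.5)
        assert part.n_communities == 2
        assert part.community_of["A"] == part.community_of["B"] == part.community_of["C"]

    def test_trivial_partition_modularity_zero(self):
        net = self.two_triangles()
        trivial = Partition(community_of={n: 0 for n in net.nodes}, n_communities=1)
        assert modularity(net, trivial) == pytest.approx(0.0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(2)
        net = net_from_graph(random_connected_graph(rng))
        first = louvain_modularity(net, seed=77)
        second = louvain_modularity(net, seed=77)
        assert first[1] == second[1]
        assert first[0].community_of == second[0].community_of

    def test_planted_two_block_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            g = nx.Graph()
            nodes = [f"n{i}" for i in range(16)]
            block = {v: i // 8 for i, v in enumerate(nodes)}
            g.add_nodes_from(nodes)
            for i, u in enumerate(nodes):
                for v in nodes[i + 1 :]:
                    p = 0.9 if block[u] == block[v] else 0.05
                    if rng.random() < p:
                        g.add_edge(u, v, weight=1)
            part, _ = louvain_modularity(net_from_graph(g), seed=seed)
            labels = [part.community_of[v] for v in nodes]
            truth = [block[v] for v in nodes]
            scores.append(adjusted_rand_score(truth, labels))
        assert np.mean(scores) >= 0.9

    def test_multicomponent_beats_trivial(self):
        rng = np.random.default_rng(4)
        g = random_connected_graph(rng)
        h = nx.relabel_nodes(random_connected_graph(rng), lambda v: f"b{v}")
        combined = nx.compose(g, h)
        _, q = louvain_modularity(net_from_graph(combined), seed=0)
        assert q > 0.0


class TestMetricsReport:
    def test_full_report_bounds(self):
        rng = np.random.default_rng(31)
        net = net_from_graph(random_connected_graph(rng))
        report = metrics_report(net, seed=0)
        frame = report.nodes_frame()
        assert frame["weighted_degree_share"].sum() == pytest.approx(100.0)
        assert ((frame["betweenness"] >= 0) & (frame["betweenness"] <= 1)).all()
        assert ((frame["eigenvector"] >= 0) & (frame["eigenvector"] <= 1)).all()
        assert 0 <= report.density <= 1
        assert report.modularity <= 1

    def test_degenerate_network_marked_undefined(self):
        g = nx.Graph()
        g.add_node("A")
        report = metrics_report(net_from_graph(g), seed=0)
        assert report.density is None
        assert "undefined" in report.note
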