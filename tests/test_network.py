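import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirpathnet import (
    GeneSetCollection,
    betweenness,
    build_network,
    closeness_and_aspl,
    clustering_coefficient,
    shortest_path_lengths,
    topological_coefficient,
    topology_report,
)
from mirpathnet.types import FormatError, RiskGeneResult
from oracles import betweenness_by_path_counting, floyd_warshall


def graph_from(edges, nodes=None):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


def pair_df(pairs):
    return pd.DataFrame(
        [(x, y, 0.9, 0.9) for x, y in pairs],
        columns=["pathway_x", "pathway_y", "r_tumor", "r_control"],
    )


class TestBuildNetwork:
    def setup_method(self):
        self.sets = GeneSetCollection(
            {"P1": ("g", "a"), "P2": ("g", "b"), "P3": ("c",)}
        )
        self.risk = RiskGeneResult(pairs=[("m", "g")], n_de_mirnas_with_targets=1,
                                   n_targets_of_de_mirnas=1)

    def test_toy_construction_rule(self):
        net = build_network(pair_df([("P1", "P2")]), self.risk, self.sets)
        assert set(net.nodes()) == {"m", "g", "P1", "P2"}
        assert {frozenset(e) for e in net.edges()} == {
            frozenset({"m", "g"}), frozenset({"g", "P1"}),
            frozenset({"g", "P2"}), frozenset({"P1", "P2"}),
        }
        assert net.degree("g") == 3
        assert net.nodes["m"]["node_type"] == "mirna"
        assert net.nodes["P1"]["node_type"] == "pathway"

    def test_pair_without_common_risk_gene_contributes_nothing(self):
        net = build_network(pair_df([("P1", "P3")]), self.risk, self.sets)
        assert net.number_of_nodes() == 0

    def test_gene_in_only_one_pathway_excluded(self):
        sets = GeneSetCollection({"P1": ("g",), "P2": ("x",)})
        net = build_network(pair_df([("P1", "P2")]), self.risk, sets)
        assert net.number_of_nodes() == 0

    def test_pathway_pathway_edges_can_be_disabled(self):
        net = build_network(pair_df([("P1", "P2")]), self.risk, self.sets,
                            include_pathway_pathway_edges=False)
        assert frozenset({"P1", "P2"}) not in {frozenset(e) for e in net.edges()}

    def test_unknown_pathway_raises(self):
        with pytest.raises(FormatError, match="P9"):
            build_network(pair_df([("P1", "P9")]), self.risk, self.sets)

    def test_invariant_to_pair_row_order(self):
        pairs = pair_df([("P1", "P2"), ("P1", "P3")])
        net_a = build_network(pairs, self.risk, self.sets)
        net_b = build_network(pairs.iloc[::-1], self.risk, self.sets)
        assert set(net_a.edges()) == set(net_b.edges())


class TestShortestPaths:
    def test_path_graph(self):
        g = graph_from([("a", "b"), ("b", "c")])
        assert shortest_path_lengths(g, "a") == {"a": 0, "b": 1, "c": 2}

    def test_disconnected_node_absent(self):
        g = graph_from([("a", "b")], nodes=["a", "b", "z"])
        assert "z" not in shortest_path_lengths(g, "a")

    def test_unknown_node_raises(self):
        with pytest.raises(KeyError):
            shortest_path_lengths(graph_from([("a", "b")]), "q")


class TestMetricsHandExamples:
    def test_betweenness_path_and_star(self):
        path = graph_from([("a", "b"), ("b", "c")])
        assert betweenness(path)["b"] == pytest.approx(1.0)
        star = graph_from([("c", f"l{i}") for i in range(4)])
        b = betweenness(star)
        assert b["c"] == pytest.approx(1.0)
        assert all(b[f"l{i}"] == 0.0 for i in range(4))

    def test_closeness_and_aspl_examples(self):
        path = graph_from([("a", "b"), ("b", "c")])
        close, aspl = closeness_and_aspl(path)
        assert aspl["a"] == pytest.approx(1.5)
        assert close["a"] == pytest.approx(2 / 3)
        k4 = graph_from([(i, j) for i in range(4) for j in range(i + 1, 4)])
        close, aspl = closeness_and_aspl(k4)
        assert all(aspl[v] == 1.0 and close[v] == 1.0 for v in k4)

    def test_isolated_node_closeness_zero(self):
        g = graph_from([("a", "b")], nodes=["a", "b", "z"])
        close, aspl = closeness_and_aspl(g)
        assert close["z"] == 0.0
        assert math.isnan(aspl["z"])

    def test_clustering_triangle_and_star(self):
        tri = graph_from([("a", "b"), ("b", "c"), ("a", "c")])
        assert clustering_coefficient(tri) == {"a": 1.0, "b": 1.0, "c": 1.0}
        star = graph_from([("c", f"l{i}") for i in range(4)])
        assert clustering_coefficient(star)["c"] == 0.0

    def test_topological_coefficient_conventions(self):
        # degree-1 node -> 0
        assert topological_coefficient(graph_from([("a", "b")]))["a"] == 0.0
        # 4-cycle: only the opposite node shares neighbors, J = 2, k = 2
        cyc = graph_from([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        assert all(v == pytest.approx(1.0) for v in topological_coefficient(cyc).values())
        # triangle: each other node shares 1 neighbor + direct link, J = 2, k = 2
        tri = graph_from([("a", "b"), ("b", "c"), ("a", "c")])
        assert all(v == pytest.approx(1.0) for v in topological_coefficient(tri).values())


class TestMetricsAgainstOracles:
    @pytest.mark.parametrize("seed,p", [(s, p) for s in range(10) for p in (0.2, 0.5)])
    def test_random_graphs_match_oracles_and_networkx(self, seed, p):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 26))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in range(n)})
        nodes = list(g.nodes())
        dist, idx = floyd_warshall(nodes, list(g.edges()))

        # distances
        for s in nodes:
            mine = shortest_path_lengths(g, s)
            for t in nodes:
                d = dist[idx[s], idx[t]]
                if np.isfinite(d):
                    assert mine[t] == d
                else:
                    assert t not in mine

        # betweenness: brute-force path counting AND networkx
        mine = betweenness(g)
        brute = betweenness_by_path_counting(nodes, list(g.edges()))
        nx_bc = nx.betweenness_centrality(g, normalized=True)
        for v in nodes:
            assert mine[v] == pytest.approx(brute[v], abs=1e-9)
            assert mine[v] == pytest.approx(nx_bc[v], abs=1e-9)

        # closeness / ASPL from the distance matrix
        close, aspl = closeness_and_aspl(g)
        for v in nodes:
            finite = [dist[idx[v], idx[t]] for t in nodes
                      if t != v and np.isfinite(dist[idx[v], idx[t]])]
            if finite:
                assert aspl[v] == pytest.approx(np.mean(finite), abs=1e-9)
                assert close[v] == pytest.approx(1 / np.mean(finite), abs=1e-9)
            else:
                assert close[v] == 0.0

        # clustering vs networkx
        nx_cc = nx.clustering(g)
        mine_cc = clustering_coefficient(g)
        for v in nodes:
            assert mine_cc[v] == pytest.approx(nx_cc[v], abs=1e-9)

        # topological coefficient vs direct neighbor-set arithmetic
        mine_tc = topological_coefficient(g)
        for v in nodes:
            nv = set(g.neighbors(v))
            if len(nv) < 2:
                assert mine_tc[v] == 0.0
                continue
            js = []
            for m in nodes:
                if m == v:
                    continue
                shared = nv & set(g.neighbors(m))
                if shared:
                    js.append(len(shared) + (1 if g.has_edge(v, m) else 0))
            expected = (np.mean(js) / len(nv)) if js else 0.0
            assert mine_tc[v] == pytest.approx(expected, abs=1e-9)


class TestTopologyReport:
    def test_toy_degrees_and_composition(self):
        sets = GeneSetCollection({"P1": ("g", "a"), "P2": ("g", "b")})
        risk = RiskGeneResult(pairs=[("m", "g")], n_de_mirnas_with_targets=1,
                              n_targets_of_de_mirnas=1)
        net = build_network(pair_df([("P1", "P2")]), risk, sets)
        report = topology_report(net)
        degrees = dict(zip(report["node"], report["degree"]))
        assert degrees == {"m": 1, "g": 3, "P1": 2, "P2": 2}
        # columns match the individual metric functions
        btw = betweenness(net)
        for _, row in report.iterrows():
            assert row["betweenness"] == pytest.approx(btw[row["node"]])

    def test_empty_network(self):
        report = topology_report(nx.Graph())
        assert report.empty

    def test_sorted_by_degree_then_id(self, small_sim):
        _, (mrna, _, sets, targets, truth) = small_sim
        report = topology_report(graph_from([("a", "b"), ("a", "c"), ("b", "c"), ("d", "a")]))
        assert list(report["node"])[0] == "a"
        keys = list(zip(-report["degree"], report["node"]))
        assert keys == sorted(keys)
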