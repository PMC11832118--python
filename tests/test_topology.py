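"""Network construction, degree, components, neighborhoods, radiality."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mitonet import (
    SyntheticSpec,
    build_network,
    connected_components,
    correlation_matrix,
    degree,
    degree_histogram,
    generate_expression,
    neighbors,
    pcit_significance,
    radiality,
    threshold_edges,
    topology_report,
)

from conftest import radiality_oracle


def edges_frame(pairs, weight=0.8):
    return pd.DataFrame(
        [(a, b, weight) for a, b in pairs], columns=["gene_a", "gene_b", "weight"]
    )


def star(n_leaves):
    return build_network(edges_frame([("C", f"L{i}") for i in range(n_leaves)]))


class TestBuildNetwork:
    def test_nodes_are_exactly_edge_endpoints(self):
        net = build_network(edges_frame([("a", "b"), ("b", "c"), ("c", "d")]))
        assert sorted(net.nodes) == ["a", "b", "c", "d"]
        assert net.number_of_edges() == 3

    def test_empty_edge_list_gives_empty_network(self):
        net = build_network(edges_frame([]))
        assert net.number_of_nodes() == 0

    def test_duplicate_edge_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_network(edges_frame([("a", "b"), ("b", "a")]))

    def test_self_edge_rejected(self):
        with pytest.raises(ValueError, match="self-edge"):
            build_network(edges_frame([("a", "a")]))

    def test_catalog_attributes_attached_with_defaults(self):
        catalog = pd.DataFrame(
            {"block_id": ["m1"], "is_anchor": [True], "is_tf": [False],
             "is_organelle_encoded": [False], "localization": ["matrix"]},
            index=pd.Index(["a"], name="gene_id"),
        )
        net = build_network(edges_frame([("a", "b")]), catalog)
        assert net.nodes["a"]["localization"] == "matrix"
        assert net.nodes["b"]["localization"] == "unknown"
        assert net.nodes["b"]["is_anchor"] is False


class TestDegree:
    def test_star_degrees(self):
        net = star(7)
        deg = degree(net)
        assert deg["C"] == 7
        assert all(deg[f"L{i}"] == 1 for i in range(7))
        assert degree_histogram(net) == {1: 7, 7: 1}

    @pytest.mark.parametrize("seed", [0, 1])
    def test_handshake_lemma_on_random_graph(self, seed):
        g = nx.gnp_random_graph(30, 0.2, seed=seed)
        net = build_network(edges_frame([(f"n{a}", f"n{b}") for a, b in g.edges]))
        assert sum(degree(net).values()) == 2 * net.number_of_edges()

    def test_heavy_tailed_degree_fixture(self):
        """Configuration-model graph with power-law-ish degrees: hub degree
        dwarfs the median (a fixture-level scale-free sanity check)."""
        rng = np.random.default_rng(0)
        seq = np.minimum(rng.zipf(2.0, size=1000), 200)
        if seq.sum() % 2:
            seq[0] += 1
        g = nx.Graph(nx.configuration_model(seq, seed=1))
        g.remove_edges_from(nx.selfloop_edges(g))
        net = build_network(edges_frame([(f"n{a}", f"n{b}") for a, b in g.edges]))
        degrees = np.array(list(degree(net).values()))
        assert degrees.max() / np.median(degrees) >= 10


class TestComponents:
    def test_two_disjoint_triangles(self):
        net = build_network(
            edges_frame([("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")])
        )
        comps = connected_components(net)
        assert [len(c) for c in comps] == [3, 3]
        assert comps[0] == ["a", "b", "c"]  # size tie broken on first node id

    def test_planted_isolated_cluster_is_own_component(self):
        spec = SyntheticSpec(
            n_samples=150, modules=((10, 0.85),), n_background_genes=5,
            isolated_cluster_size=8, tf_count=0, n_low_expression=0, seed=2,
        )
        expr, catalog = generate_expression(spec)
        edges = threshold_edges(pcit_significance(correlation_matrix(expr)), 0.7)
        net = build_network(edges, catalog)
        isolated = set(catalog.index[catalog["block_id"] == "isolated"])
        comps = [set(c) for c in connected_components(net)]
        assert any(c <= isolated and len(c) > 1 for c in comps)
        # no edge leaves the planted cluster
        assert all(c <= isolated or not (c & isolated) for c in comps)


class TestNeighbors:
    def test_star_center_and_leaf(self):
        net = star(4)
        assert neighbors(net, "C") == ["L0", "L1", "L2", "L3"]
        assert neighbors(net, "L2") == ["C"]

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            neighbors(star(3), "missing")


class TestRadiality:
    def test_star_center_closed_form(self):
        assert radiality(star(4))["C"] == pytest.approx(1.0)

    def test_star_on_five_leaf_closed_form(self):
        # leaf: mean distance (1+2+2+2)/4 = 1.75, diameter 2 -> (3-1.75)/2
        assert radiality(star(4))["L0"] == pytest.approx(0.625)

    def test_complete_graph_all_ones(self):
        pairs = [(f"n{i}", f"n{j}") for i in range(5) for j in range(i + 1, 5)]
        rad = radiality(build_network(edges_frame(pairs)))
        assert all(v == pytest.approx(1.0) for v in rad.values())

    def test_bounds_and_adjacency_characterisation(self):
        g = nx.gnp_random_graph(25, 0.15, seed=5)
        net = build_network(edges_frame([(f"n{a}", f"n{b}") for a, b in g.edges]))
        rad = radiality(net)
        comps = {n: i for i, c in enumerate(connected_components(net)) for n in c}
        sizes = [len(c) for c in connected_components(net)]
        for node, value in rad.items():
            if sizes[comps[node]] == 1:
                assert math.isnan(value)
            else:
                assert 0.0 <= value <= 1.0 + 1e-12
                if value == pytest.approx(1.0):
                    assert net.degree(node) == sizes[comps[node]] - 1

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_floyd_warshall_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 41))
        g = nx.gnp_random_graph(n, 0.15, seed=seed + 100)
        net = build_network(edges_frame([(f"n{a:02d}", f"n{b:02d}") for a, b in g.edges]))
        if net.number_of_nodes() == 0:
            pytest.skip("empty random draw")
        expected = radiality_oracle(net)
        actual = radiality(net)
        assert actual.keys() == expected.keys()
        for node in expected:
            if math.isnan(expected[node]):
                assert math.isnan(actual[node])
            else:
                assert actual[node] == pytest.approx(expected[node], abs=1e-12)


class TestReport:
    def test_report_consistency(self):
        net = build_network(edges_frame([("a", "b"), ("b", "c"), ("x", "y")]))
        report = topology_report(net)
        assert report.n_nodes == 5
        assert report.component_sizes == (3, 2)
        assert report.nodes["degree"].sum() == 2 * net.number_of_edges()
        assert set(report.nodes["component"]) == {0, 1}
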