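"""LCA table vs brute-force oracle, multi-element reduction, both discovery
methods, and triple generation."""

import random

import networkx as nx
import pytest

from ontoqa import association as am
from ontoqa import fixtures as fx
from ontoqa import ontology as om
from ontoqa.preprocess import ComparativeRelation


def brute_force_lca(g: nx.DiGraph):
    """Oracle: enumerate common ancestors per pair, minimize ancestral
    distance with per-pair shortest-path queries."""
    nodes = sorted(g.nodes)
    table = {}
    for i, x in enumerate(nodes):
        for y in nodes[i:]:
            best, bestd = set(), None
            for c in nodes:
                anc_of_x = c == x or nx.has_path(g, c, x)
                anc_of_y = c == y or nx.has_path(g, c, y)
                if anc_of_x and anc_of_y:
                    d = (nx.shortest_path_length(g, c, x)
                         + nx.shortest_path_length(g, c, y))
                    if bestd is None or d < bestd:
                        best, bestd = {c}, d
                    elif d == bestd:
                        best.add(c)
            if bestd is not None:
                table[(x, y)] = (best, bestd)
    return table


def make_dag(seed, max_nodes=50):
    rng = random.Random(seed)
    n = rng.randint(4, max_nodes)
    g = nx.MultiDiGraph()
    nodes = [f"n{i:02d}" for i in range(n)]
    g.add_nodes_from(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.1:
                g.add_edge(nodes[i], nodes[j], key="p", label="p",
                           instantiated=True)
    return om.AcyclicGraph(g, {})


class TestLcaTable:
    def test_chain_ancestor_is_its_own_lca(self):
        g = nx.MultiDiGraph()
        g.add_edge("A", "B", key="p", label="p")
        g.add_edge("B", "C", key="p", label="p")
        table = am.build_lca_table(om.AcyclicGraph(g, {}))
        assert table.lcas("B", "C") == ({"B"}, 1)
        assert table.lcas("B", "B")[0] == {"B"}

    def test_diamond_forces_top(self):
        g = nx.MultiDiGraph()
        for u, v in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
            g.add_edge(u, v, key="p", label="p")
        table = am.build_lca_table(om.AcyclicGraph(g, {}))
        assert table.lcas("B", "C") == ({"A"}, 2)

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_brute_force_oracle(self, seed):
        ag = make_dag(seed)
        table = am.build_lca_table(ag)
        oracle = brute_force_lca(nx.DiGraph(ag.graph))
        cells = {k: (v[0], v[1]) for k, v in table.table.items()}
        assert cells == oracle

    def test_cyclic_input_rejected(self):
        g = nx.MultiDiGraph()
        g.add_edge("A", "B", key="p", label="p")
        g.add_edge("B", "A", key="p", label="p")
        with pytest.raises(ValueError):
            am.build_lca_table(om.AcyclicGraph(g, {}))

    def test_serialization_round_trip_and_stale_hash(self, dag, lca_table):
        clone = am.LcaTable.from_json(lca_table.to_json())
        assert clone.table == lca_table.table
        clone.check(dag)
        other = make_dag(1)
        with pytest.raises(am.StaleTableError):
            clone.check(other)


class TestMultiLca:
    def test_singleton(self, lca_table):
        assert am.multi_lca([fx.iri("gene")], lca_table) == fx.iri("gene")

    def test_ancestor_pair(self, lca_table):
        anc = am.multi_lca([fx.iri("gene"), fx.iri("biological material")],
                           lca_table)
        assert anc == fx.iri("biological material")

    def test_chain_example_hub_is_cell_cloning(self, lca_table):
        hub = am.multi_lca([fx.iri("cell cloning"), fx.iri("gene")], lca_table)
        assert hub == fx.iri("cell cloning")

    def test_fork_example_hub_is_proteome_analysis(self, lca_table):
        hub = am.multi_lca([fx.iri("five prime forward region"),
                            fx.iri("spectral count"),
                            fx.iri("proteome analysis")], lca_table)
        assert hub == fx.iri("proteome analysis")

    def test_four_branch_example_reduces_to_process(self, lca_table):
        hub = am.multi_lca([fx.iri("spectral count"), fx.iri("gene"),
                            fx.iri("pathway"), fx.iri("experiment justification")],
                           lca_table)
        assert hub == fx.iri("process")

    def test_disconnected_elements_fail_loudly(self):
        g = nx.MultiDiGraph()
        g.add_nodes_from(["A", "B"])
        table = am.build_lca_table(om.AcyclicGraph(g, {}))
        with pytest.raises(am.NoAssociationError):
            am.multi_lca(["A", "B"], table)


class TestDiscoverLca:
    def test_trivial_path_when_hub_is_element(self, dag, lca_table):
        assoc = am.discover_lca([fx.iri("gene"), fx.iri("spectral count")],
                                [], dag, lca_table)
        assert assoc.hub == fx.iri("gene")
        assert assoc.paths[fx.iri("gene")] == []
        assert len(assoc.paths[fx.iri("spectral count")]) == 1

    def test_hub_on_every_path(self, dag, lca_table):
        assoc = am.discover_lca(
            [fx.iri("five prime forward region"), fx.iri("spectral count"),
             fx.iri("proteome analysis")], [], dag, lca_table)
        for el, path in assoc.paths.items():
            if path:
                assert path[0][0] == assoc.hub
                assert path[-1][2] == el

    @pytest.mark.parametrize("seed", range(10))
    def test_path_lengths_match_bfs_oracle(self, seed):
        ag = make_dag(seed, max_nodes=30)
        table = am.build_lca_table(ag)
        g = nx.DiGraph(ag.graph)
        rng = random.Random(seed)
        nodes = sorted(ag.graph.nodes)
        elements = rng.sample(nodes, min(3, len(nodes)))
        try:
            assoc = am.discover_lca(elements, [], ag, table)
        except am.NoAssociationError:
            return
        for el, path in assoc.paths.items():
            assert len(path) == nx.shortest_path_length(g, assoc.hub, el)

    def test_required_property_preferred_on_ties(self):
        g = nx.MultiDiGraph()
        g.add_edge("A", "B", key="p", label="p", instantiated=True)
        g.add_edge("A", "B", key="q", label="q", instantiated=True)
        ag = om.AcyclicGraph(g, {})
        table = am.build_lca_table(ag)
        assoc = am.discover_lca(["A", "B"], ["q"], ag, table)
        assert assoc.paths["B"] == [("A", "q", "B")]
        assert assoc.included_properties == ["q"]


class TestDiscoverPaths:
    def test_diamond_common_node(self):
        g = nx.MultiDiGraph()
        for u, v in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
            g.add_edge(u, v, key="p", label="p", instantiated=True)
        assoc = am.discover_paths(["B", "C"], om.AcyclicGraph(g, {}))
        assert assoc.hub == "A"

    def test_agrees_with_lca_on_fork_example(self, dag, lca_table):
        elements = [fx.iri("five prime forward region"), fx.iri("spectral count"),
                    fx.iri("proteome analysis")]
        assert am.discover_paths(elements, dag).hub == \
            am.discover_lca(elements, [], dag, lca_table).hub

    @pytest.mark.parametrize("seed", range(20))
    def test_agrees_with_lca_when_unique_minimal_ancestor_exists(self, seed):
        ag = make_dag(seed, max_nodes=15)
        table = am.build_lca_table(ag)
        rng = random.Random(seed + 100)
        nodes = sorted(ag.graph.nodes)
        elements = rng.sample(nodes, 2)
        lcas, _ = table.lcas(*elements)
        if len(lcas) != 1:
            return
        try:
            hub2 = am.discover_paths(elements, ag).hub
        except am.NoAssociationError:
            return
        assert hub2 == am.discover_lca(elements, [], ag, table).hub

    def test_no_common_node_fails(self):
        g = nx.MultiDiGraph()
        g.add_nodes_from(["A", "B"])
        with pytest.raises((am.NoAssociationError, ValueError)):
            am.discover_paths(["A", "B"], om.AcyclicGraph(g, {}))


class TestToTriples:
    def test_property_edges_become_patterns(self, dag, lca_table, model):
        assoc = am.discover_lca([fx.iri("gene"), fx.iri("spectral count")],
                                [], dag, lca_table)
        ts = am.to_triples(assoc, [], dag.split_map, model)
        assert (ts.triples[0][1] == fx.iri("has measurement"))
        assert set(ts.var_classes.values()) == {fx.iri("gene"),
                                                fx.iri("spectral count")}

    def test_comparatives_bind_shared_literal_variable(self, dag, lca_table, model):
        assoc = am.discover_lca([fx.iri("gene"), fx.iri("spectral count")],
                                [], dag, lca_table)
        comps = [ComparativeRelation("spectral count", ">", 40),
                 ComparativeRelation("spectral count", "<", 50)]
        ts = am.to_triples(assoc, comps, dag.split_map, model)
        assert [f[0] for f in ts.filters] == ["?lit0", "?lit0"]
        assert [(f[1], f[2]) for f in ts.filters] == [(">", 40), ("<", 50)]

    def test_split_nodes_projected_to_original_iri(self, dag, model):
        split = fx.iri("data collection") + "_1"
        assert split in dag.split_map
        original = dag.split_map[split]
        assoc = am.SemanticAssociation(
            fx.iri("parameter"),
            {original: [(fx.iri("parameter"), fx.iri("transformation of"), split)]})
        ts = am.to_triples(assoc, [], dag.split_map, model)
        joined = " ".join(str(t) for t in ts.triples) + " ".join(ts.var_classes.values())
        assert split not in joined
        assert original in ts.var_classes.values()

    def test_unbound_comparative_raises(self, dag, lca_table, model):
        assoc = am.discover_lca([fx.iri("gene"), fx.iri("pathway")],
                                [], dag, lca_table)
        with pytest.raises(am.UnboundFilterError):
            am.to_triples(assoc, [ComparativeRelation("zzqq metric", ">", 1)],
                          dag.split_map, model)
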