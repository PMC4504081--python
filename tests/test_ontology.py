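"""Ontology loading, property graph construction, cycle breaking, subtrees."""

import random

import networkx as nx
import pytest
import rdflib
from rdflib import OWL, RDF, RDFS, Namespace

from ontoqa import fixtures as fx
from ontoqa import ontology as om

EX = Namespace("http://example.org/t#")


def small_graph(triples):
    g = rdflib.Graph()
    for t in triples:
        g.add(t)
    return g


class TestLoadOntology:
    def test_fixture_counts_match_document(self, model, fixture):
        assert len(model.classes) == len(fixture.class_names)
        assert len(model.properties) == len(fixture.property_names)
        assert model.root == fx.iri("entity")
        assert [model.name_of(u) for u in model.upper_labels] == list(fx.UPPER_LABELS)

    def test_annotations_captured(self, model):
        sc = fx.iri("spectral count")
        assert model.label_of(sc) == "spectral count"
        assert "spectra score" in model.comment_of(sc)

    def test_single_class_document(self):
        g = small_graph([(EX.C, RDF.type, OWL.Class)])
        m = om.load_ontology(g)
        assert m.classes == {str(EX.C)} and m.root == str(EX.C)

    def test_empty_document_with_labels_is_config_error(self):
        with pytest.raises(om.OntologyConfigError):
            om.load_ontology(rdflib.Graph(), ["anything"])

    def test_unresolvable_upper_label_names_offender(self):
        g = small_graph([(EX.C, RDF.type, OWL.Class)])
        with pytest.raises(om.OntologyConfigError, match="no-such-label"):
            om.load_ontology(g, ["no-such-label"])

    def test_unparseable_document_is_format_error(self, tmp_path):
        bad = tmp_path / "bad.ttl"
        bad.write_text("this is not turtle {{{")
        with pytest.raises(om.OntologyFormatError):
            om.load_ontology(bad)

    def test_multiple_roots_get_synthetic_parent(self):
        g = small_graph([(EX.A, RDF.type, OWL.Class), (EX.B, RDF.type, OWL.Class)])
        m = om.load_ontology(g)
        assert m.root == om.SYNTHETIC_ROOT
        assert m.parents_of(str(EX.A)) == {om.SYNTHETIC_ROOT}


class TestPropertyGraph:
    def test_subclass_edge_runs_parent_to_child(self, graph):
        assert graph.has_edge(fx.iri("material"), fx.iri("biological material"),
                              key=om.SUBCLASS)

    def test_object_property_edge_domain_to_range(self, graph):
        assert graph.has_edge(fx.iri("gene"), fx.iri("spectral count"),
                              key=fx.iri("has measurement"))

    def test_datatype_properties_are_not_edges(self, graph):
        labels = {d["label"] for _, _, d in graph.edges(data=True)}
        assert fx.iri("has value") not in labels

    def test_instantiated_flags_reflect_data(self, graph, fixture):
        preds_in_data = {str(p) for p in fixture.data.predicates(None, None)}
        for _, _, d in graph.edges(data=True):
            if d["kind"] == "property":
                assert d["instantiated"] == (d["label"] in preds_in_data)

    def test_without_data_all_flags_true(self, model):
        g = om.build_property_graph(model, data=None)
        assert all(d["instantiated"] for _, _, d in g.edges(data=True))


def _random_digraph(seed, n=50, p=0.1):
    rng = random.Random(seed)
    g = nx.MultiDiGraph()
    nodes = [f"n{i:02d}" for i in range(rng.randint(5, n))]
    g.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < p:
                g.add_edge(u, v, key=f"p{rng.randint(0, 3)}",
                           label=f"p{rng.randint(0, 3)}", kind="property",
                           instantiated=True)
    return g


class TestToDag:
    @pytest.mark.parametrize("seed", range(30))
    def test_random_graphs_acyclic_and_projection_exact(self, seed):
        g = _random_digraph(seed)
        ag = om.to_dag(g)
        assert nx.is_directed_acyclic_graph(ag.graph)
        original = sorted((u, d["label"], v) for u, v, d in g.edges(data=True))
        assert ag.projected_edges() == original

    def test_deterministic(self):
        g = _random_digraph(99)
        a, b = om.to_dag(g), om.to_dag(g)
        assert sorted(a.graph.nodes) == sorted(b.graph.nodes)
        assert sorted(a.graph.edges(keys=True)) == sorted(b.graph.edges(keys=True))
        assert a.split_map == b.split_map

    def test_acyclic_input_is_identity(self):
        g = nx.MultiDiGraph()
        g.add_edge("a", "b", key="p", label="p")
        g.add_edge("a", "c", key="p", label="p")
        g.add_edge("b", "d", key="p", label="p")
        g.add_edge("c", "d", key="p", label="p")
        ag = om.to_dag(g)
        assert ag.split_map == {}
        assert sorted(ag.graph.edges(keys=True)) == sorted(g.edges(keys=True))

    def test_cycle_closing_edge_rerouted_to_suffixed_node(self):
        # parameter <-> data collection two-edge cycle: the regenerated
        # graph reroutes the closing edge to "data collection_1"
        g = nx.MultiDiGraph()
        g.add_edge("data collection", "parameter", key="has parameter",
                   label="has parameter")
        g.add_edge("parameter", "data collection", key="transformation of",
                   label="transformation of")
        ag = om.to_dag(g)
        assert nx.is_directed_acyclic_graph(ag.graph)
        assert ag.split_map == {"data collection_1": "data collection"}
        assert ag.graph.has_edge("parameter", "data collection_1",
                                 key="transformation of")

    def test_fixture_splits_project_back(self, graph, dag):
        assert len(dag.split_map) == 3
        original = sorted((u, d["label"], v) for u, v, d in graph.edges(data=True))
        assert dag.projected_edges() == original


class TestSubtreeElements:
    def test_contains_self_and_nested_in_root_subtree(self, model):
        root_set = om.subtree_elements(model, model.upper_labels[0])
        for c in model.upper_labels:
            s = om.subtree_elements(model, c)
            assert c in s

    def test_whole_hierarchy_under_root_label(self, fixture, spec):
        m = om.load_ontology(fixture.ontology, ["entity"])
        s = om.subtree_elements(m, "entity")
        assert m.classes <= s

    def test_leaf_class_subtree(self, fixture):
        m = om.load_ontology(fixture.ontology, ["metabolic pathway"])
        assert om.subtree_elements(m, "metabolic pathway") == {fx.iri("metabolic pathway")}

    def test_transitive_closure_matches_gold(self, model, fixture):
        for upper_name, gold_names in fixture.subtree_gold.items():
            s = om.subtree_elements(model, upper_name)
            classes = {model.name_of(e) for e in s if e in model.classes}
            assert classes == gold_names

    def test_non_upper_label_rejected(self, model):
        with pytest.raises(om.OntologyConfigError):
            om.subtree_elements(model, "spectral count")
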