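"""Ontology loading and graph construction.

This module turns an OWL/RDFS ontology document into the three in-memory
structures the rest of the pipeline consumes:

``OntologyModel``
    the declared classes, properties, subclass axioms and annotation
    strings, plus the ordered set ``C_O`` of designated *upper-level*
    elements that serve as entity-recognition labels.

``PropertyGraph``
    a directed labeled graph over the classes: one edge per subclass axiom
    (parent -> child) and one edge per (domain, property, range) triple of
    every object property.  When instance data is supplied, each property
    edge carries an ``instantiated`` flag recording whether at least one
    data triple uses the predicate.

``AcyclicGraph``
    the cycle-broken version of the property graph required by the
    lowest-common-ancestor machinery.  Cycles are removed by *splitting*
    the node that closes a cycle into a fresh node named
    ``<original>_<k>`` with no outgoing edges; a split map records the
    provenance so paths can be projected back onto original classes.

Subclass edges run parent -> child so that an *ancestor* is any node on a
directed path from the root; property edges run domain -> range.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import rdflib
from rdflib import OWL, RDF, RDFS

logger = logging.getLogger(__name__)

#: reserved edge label marking a subclass (parent -> child) edge
SUBCLASS = "rdfs:subClassOf"

#: identifier of the synthetic root inserted when several classes lack parents
SYNTHETIC_ROOT = "owl:Thing"


class OntologyFormatError(ValueError):
    """The ontology document could not be parsed or is structurally empty."""


class OntologyConfigError(ValueError):
    """A configured upper-level label does not resolve to a declared element."""


@dataclass(frozen=True)
class OntologyProperty:
    """A declared object or datatype property with its domain/range classes."""

    iri: str
    kind: str  # "object" | "datatype"
    domains: frozenset = frozenset()
    ranges: frozenset = frozenset()


@dataclass
class OntologyModel:
    """Parsed ontology: classes, properties, subclass axioms, annotations, C_O."""

    classes: set = field(default_factory=set)
    properties: dict = field(default_factory=dict)  # iri -> OntologyProperty
    subclass_edges: set = field(default_factory=set)  # (child, parent)
    annotations: dict = field(default_factory=dict)  # iri -> {name,label,comment}
    upper_labels: list = field(default_factory=list)  # ordered C_O
    root: str | None = None

    def name_of(self, element: str) -> str:
        """Human-readable name of an element (rdfs:label, else local name)."""
        ann = self.annotations.get(element, {})
        return ann.get("name") or local_name(element)

    def label_of(self, element: str) -> str | None:
        return self.annotations.get(element, {}).get("label")

    def comment_of(self, element: str) -> str | None:
        return self.annotations.get(element, {}).get("comment")

    def parents_of(self, cls: str) -> set:
        return {p for (c, p) in self.subclass_edges if c == cls}

    def children_of(self, cls: str) -> set:
        return {c for (c, p) in self.subclass_edges if p == cls}

    def elements(self) -> set:
        """All classes and properties (the matching search space)."""
        return set(self.classes) | set(self.properties)

    def resolve_upper(self, label: str) -> str | None:
        """Map an upper-level label given as IRI or name to its IRI."""
        if label in self.upper_labels:
            return label
        low = str(label).lower()
        for el in self.upper_labels:
            if self.name_of(el).lower() == low:
                return el
        return None


def local_name(iri: str) -> str:
    """Local name of an IRI with underscores mapped to spaces."""
    for sep in ("#", "/"):
        if sep in iri:
            iri = iri.rsplit(sep, 1)[1]
    return iri.replace("_", " ")


def _guess_format(path: str) -> str:
    if str(path).endswith((".ttl", ".n3")):
        return "turtle"
    if str(path).endswith(".nt"):
        return "nt"
    return "xml"


def load_ontology(document, upper_label_config: list[str] | None = None) -> OntologyModel:
    """Load an OWL/RDFS document (RDF/XML or Turtle) into an :class:`OntologyModel`.

    Parameters
    ----------
    document:
        Path to the ontology file, or an already-parsed :class:`rdflib.Graph`.
    upper_label_config:
        Ordered element names (or IRIs) designating the upper-level label set
        ``C_O``.  Each must resolve to a declared class or property.

    Raises
    ------
    OntologyFormatError
        if the document cannot be parsed, or declares no classes while
        labels were requested.
    OntologyConfigError
        if an upper label fails to resolve; the offender is named.
    """
    if isinstance(document, rdflib.Graph):
        g = document
    else:
        g = rdflib.Graph()
        try:
            g.parse(str(document), format=_guess_format(str(document)))
        except Exception as exc:  # rdflib raises many parser-specific errors
            raise OntologyFormatError(f"cannot parse ontology document {document!r}: {exc}") from exc

    model = OntologyModel()

    for cls in set(g.subjects(RDF.type, OWL.Class)) | set(g.subjects(RDF.type, RDFS.Class)):
        if isinstance(cls, rdflib.URIRef):
            model.classes.add(str(cls))
    for child, parent in g.subject_objects(RDFS.subClassOf):
        if isinstance(child, rdflib.URIRef) and isinstance(parent, rdflib.URIRef):
            model.classes.update((str(child), str(parent)))
            model.subclass_edges.add((str(child), str(parent)))

    for kind, rdf_kind in (("object", OWL.ObjectProperty), ("datatype", OWL.DatatypeProperty)):
        for prop in g.subjects(RDF.type, rdf_kind):
            if not isinstance(prop, rdflib.URIRef):
                continue
            domains = frozenset(str(d) for d in g.objects(prop, RDFS.domain) if isinstance(d, rdflib.URIRef))
            ranges = frozenset(str(r) for r in g.objects(prop, RDFS.range) if isinstance(r, rdflib.URIRef))
            model.properties[str(prop)] = OntologyProperty(str(prop), kind, domains, ranges)

    for el in set(model.classes) | set(model.properties):
        ref = rdflib.URIRef(el)
        label = g.value(ref, RDFS.label)
        comment = g.value(ref, RDFS.comment)
        model.annotations[el] = {
            "name": local_name(el),
            "label": str(label) if label is not None else None,
            "comment": str(comment) if comment is not None else None,
        }

    # root: the unique parentless class; several -> synthetic owl:Thing above them
    parentless = sorted(c for c in model.classes if not model.parents_of(c))
    if len(parentless) == 1:
        model.root = parentless[0]
    elif len(parentless) > 1:
        model.root = SYNTHETIC_ROOT
        model.classes.add(SYNTHETIC_ROOT)
        model.annotations[SYNTHETIC_ROOT] = {"name": "thing", "label": None, "comment": None}
        for c in parentless:
            model.subclass_edges.add((c, SYNTHETIC_ROOT))

    if upper_label_config:
        if not model.classes:
            raise OntologyConfigError("ontology declares no classes; cannot resolve upper labels")
        by_name = {}
        for el in model.elements():
            by_name.setdefault(model.name_of(el).lower(), el)
            lbl = model.label_of(el)
            if lbl:
                by_name.setdefault(lbl.lower(), el)
        for name in upper_label_config:
            el = name if name in model.elements() else by_name.get(name.lower())
            if el is None:
                raise OntologyConfigError(f"upper label {name!r} does not resolve to a declared element")
            model.upper_labels.append(el)
    return model


def build_property_graph(model: OntologyModel, data: rdflib.Graph | None = None) -> nx.MultiDiGraph:
    """Build the directed labeled ontology graph over the model's classes.

    Edges: one (parent -> child) edge per subclass axiom, labeled with the
    reserved subclass marker, and one (domain -> range) edge per object
    property, labeled with the property IRI.  Datatype properties do not
    become edges; they are used only as triple predicates for FILTER
    clauses downstream.

    When ``data`` is given, each property edge's ``instantiated`` flag
    records whether the predicate occurs in at least one data triple;
    without data all flags are true.
    """
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(model.classes))
    for child, parent in sorted(model.subclass_edges):
        g.add_edge(parent, child, key=SUBCLASS, label=SUBCLASS, kind="subclass", instantiated=True)

    instantiated_preds = None
    if data is not None:
        instantiated_preds = {str(p) for p in data.predicates(None, None)}

    for iri, prop in sorted(model.properties.items()):
        if prop.kind != "object":
            continue
        if not prop.domains or not prop.ranges:
            logger.warning("property %s lacks a declared domain or range; edge skipped", iri)
            continue
        flag = True if instantiated_preds is None else iri in instantiated_preds
        for d in sorted(prop.domains):
            for r in sorted(prop.ranges):
                if d not in model.classes or r not in model.classes:
                    logger.warning("property %s references undeclared class; edge skipped", iri)
                    continue
                g.add_edge(d, r, key=iri, label=iri, kind="property", instantiated=flag)
    return g


@dataclass
class AcyclicGraph:
    """Cycle-broken ontology graph plus split-node provenance.

    ``split_map`` sends each split-node id (``"<original>_<k>"``) to its
    original class; original nodes are not in the map.
    """

    graph: nx.MultiDiGraph
    split_map: dict = field(default_factory=dict)

    def project(self, node: str) -> str:
        """Original class behind ``node`` (identity for unsplit nodes)."""
        return self.split_map.get(node, node)

    def projected_edges(self):
        """Multiset of edges with split nodes projected back, as a sorted list."""
        return sorted(
            (self.project(u), data["label"], self.project(v))
            for u, v, data in self.graph.edges(data=True)
        )

    def to_edge_list(self) -> str:
        """GraphViz-style one-edge-per-line dump: source<TAB>label<TAB>target."""
        return "\n".join(
            f"{u}\t{d['label']}\t{v}" for u, v, d in sorted(self.graph.edges(data=True), key=lambda e: (e[0], e[2]["label"], e[1]))
        )

    def split_map_json(self) -> str:
        return json.dumps(self.split_map, indent=2, sort_keys=True)


def to_dag(graph: nx.MultiDiGraph, roots: list[str] | None = None) -> AcyclicGraph:
    """Break every directed cycle of ``graph`` by node splitting.

    The graph is regenerated by a depth-first traversal (nodes and
    out-edges in lexicographic order).  An edge whose insertion would
    close a directed cycle is rerouted to a *split* copy of its target,
    named ``<target>_<k>``; an existing split copy is reused whenever
    adding the edge to it creates no cycle, otherwise a new one is made.
    Split copies carry no outgoing edges, so every input edge is
    represented exactly once and projecting splits back through the split
    map recovers the input edge multiset.

    The procedure is deterministic: identical inputs give identical
    node and edge sets.
    """
    out = nx.MultiDiGraph()
    out.add_nodes_from(sorted(graph.nodes))
    split_map: dict[str, str] = {}
    split_count: dict[str, int] = {}

    def reachable(src: str, dst: str) -> bool:
        return src == dst or nx.has_path(out, src, dst)

    def add_edge(u: str, v: str, data: dict) -> None:
        # keep the original target when it closes no cycle
        if not reachable(v, u):
            out.add_edge(u, v, key=data["label"], **data)
            return
        # reuse an existing split of v when possible, in suffix order
        for k in range(1, split_count.get(v, 0) + 1):
            sv = f"{v}_{k}"
            if not reachable(sv, u):
                out.add_edge(u, sv, key=data["label"], **data)
                return
        k = split_count.get(v, 0) + 1
        split_count[v] = k
        sv = f"{v}_{k}"
        out.add_node(sv)
        split_map[sv] = v
        out.add_edge(u, sv, key=data["label"], **data)

    seen: set[str] = set()

    def visit(node: str) -> None:
        if node in seen:
            return
        seen.add(node)
        edges = sorted(
            ((v, dict(d)) for _, v, d in graph.out_edges(node, data=True)),
            key=lambda e: (e[1]["label"], e[0]),
        )
        for v, data in edges:
            add_edge(node, v, data)
        for v, _ in edges:
            visit(v)

    starts = list(roots) if roots else []
    starts += [n for n in sorted(graph.nodes) if n not in starts]
    for n in starts:
        visit(n)

    assert nx.is_directed_acyclic_graph(out)
    return AcyclicGraph(out, split_map)


def subtree_elements(model: OntologyModel, c: str) -> set:
    """The set ``S_c``: ``c`` plus all transitive subclasses and the
    properties whose declared domain lies inside that hierarchy.

    ``c`` must be a member of ``C_O``; properties in ``C_O`` root a
    singleton subtree.
    """
    resolved = model.resolve_upper(c)
    if resolved is None:
        raise OntologyConfigError(f"{c!r} is not an upper-level label")
    c = resolved
    if c in model.properties:
        return {c}
    classes = {c}
    frontier = [c]
    while frontier:
        node = frontier.pop()
        for child in model.children_of(node):
            if child not in classes:
                classes.add(child)
                frontier.append(child)
    props = {
        iri for iri, p in model.properties.items() if p.domains & classes
    }
    return classes | props
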