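"""Semantic association discovery on the cycle-broken ontology graph.

Two routes to the *hub* class that connects the matched ontology
elements:

Method 1 (``discover_lca``)
    precompute an n x n table of all-pairs lowest common ancestors under
    minimal ancestral distance (distance(c,x) + distance(c,y) minimal
    among common ancestors c), reduce a multi-element set recursively
    through pairwise LCA lookups, then take one shortest hub->element
    path per element.

Method 2 (``discover_paths``)
    enumerate bounded pairwise paths between the elements, intersect
    each combination from the Cartesian product to collect candidate
    common nodes, and keep the common node with the shortest paths to
    all elements.

Both produce a :class:`SemanticAssociation` that compiles to an ordered
RDF triple sequence; split nodes introduced by cycle breaking are
projected back to their original classes on output.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field

import networkx as nx

from .ontology import SUBCLASS, AcyclicGraph, OntologyModel
from .preprocess import ComparativeRelation
from .similarity import similarity

logger = logging.getLogger(__name__)


class NoAssociationError(ValueError):
    """No semantic association connects the given elements."""


class StaleTableError(ValueError):
    """The LCA table was built for a different graph."""


class UnboundFilterError(ValueError):
    """A comparative relation has no matched element to attach to."""


def graph_hash(ag: AcyclicGraph) -> str:
    payload = json.dumps(sorted((u, d["label"], v) for u, v, d in ag.graph.edges(data=True)))
    return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class LcaTable:
    """All-pairs LCA sets with minimal ancestral distances.

    ``table`` maps a sorted node pair to (set of LCA nodes, minimal
    ancestral distance).  ``depth`` is each node's shortest distance from
    a root, used to prefer the most specific LCA on ties.
    """

    table: dict
    depth: dict
    hash: str

    def lcas(self, x: str, y: str):
        """(set of LCAs, minimal ancestral distance) for a node pair, or
        (set(), None) when no common ancestor exists."""
        return self.table.get(tuple(sorted((x, y))), (set(), None))

    def check(self, ag: AcyclicGraph) -> None:
        if graph_hash(ag) != self.hash:
            raise StaleTableError("LCA table does not match this graph; rebuild it")

    # serialization keyed by the graph hash
    def to_json(self) -> str:
        return json.dumps({
            "hash": self.hash,
            "depth": self.depth,
            "table": [[list(k), sorted(v[0]), v[1]] for k, v in sorted(self.table.items())],
        })

    @classmethod
    def from_json(cls, text: str) -> "LcaTable":
        obj = json.loads(text)
        table = {tuple(k): (set(s), d) for k, s, d in obj["table"]}
        return cls(table, obj["depth"], obj["hash"])


def build_lca_table(ag: AcyclicGraph) -> LcaTable:
    """All-pairs LCA table for an acyclic graph.

    For every candidate ancestor c the set of nodes it reaches is
    computed once; every reachable pair (x, y) then updates its cell with
    distance(c,x) + distance(c,y), keeping the full set of minimizers.
    """
    g = ag.graph
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("LCA requires an acyclic graph; run to_dag first")
    nodes = sorted(g.nodes)
    roots = [n for n in nodes if g.in_degree(n) == 0]
    depth = {}
    for r in roots:
        for n, d in nx.single_source_shortest_path_length(g, r).items():
            if n not in depth or d < depth[n]:
                depth[n] = d
    for n in nodes:
        depth.setdefault(n, 0)

    table: dict = {}
    for c in nodes:
        reach = nx.single_source_shortest_path_length(g, c)
        members = sorted(reach)
        for i, x in enumerate(members):
            dx = reach[x]
            for y in members[i:]:
                total = dx + reach[y]
                key = (x, y)
                cur = table.get(key)
                if cur is None or total < cur[1]:
                    table[key] = ({c}, total)
                elif total == cur[1]:
                    cur[0].add(c)
    return LcaTable(table, depth, graph_hash(ag))


def _ordered_lcas(table: LcaTable, x: str, y: str) -> list:
    """Pairwise LCAs, most specific (deepest) first, then lexicographic."""
    lcas, _ = table.lcas(x, y)
    return sorted(lcas, key=lambda c: (-table.depth.get(c, 0), c))


def multi_lca(elements, table: LcaTable) -> str:
    """Reduce a set of classes to a single hub through recursive pairwise
    LCA lookups, backtracking over alternative LCAs.

    Elements are processed in sorted order by a left fold; when a
    pairwise step admits several LCAs the alternatives are explored
    most-specific-first until one leads to a full solution.  Raises
    :class:`NoAssociationError` when no reduction succeeds.
    """
    elements = sorted(set(elements))
    if not elements:
        raise ValueError("empty element set")

    def solve(items) -> str | None:
        if len(items) == 1:
            return items[0]
        x, y = items[0], items[1]
        for cand in _ordered_lcas(table, x, y):
            result = solve(sorted(set([cand] + items[2:])))
            if result is not None:
                return result
        return None

    hub = solve(elements)
    if hub is None:
        raise NoAssociationError(f"no semantic association for {elements}")
    return hub


@dataclass
class SemanticAssociation:
    """Hub class plus one path from the hub to each matched element."""

    hub: str
    paths: dict  # element -> list of (u, label, v) edges, hub -> element
    included_properties: list = field(default_factory=list)


def _best_edge_path(g: nx.MultiDiGraph, node_path: list, required: set):
    """Resolve a node path to labeled edges, preferring required
    properties, then instantiated edges, then lexicographic labels."""
    edges = []
    for u, v in zip(node_path, node_path[1:]):
        options = [
            (d["label"], bool(d.get("instantiated", True)))
            for key, d in g.get_edge_data(u, v).items()
        ]
        options.sort(key=lambda o: (o[0] not in required, not o[1], o[0]))
        edges.append((u, options[0][0], v))
    return edges


def _rank_paths(g, paths, required):
    def key(node_path):
        edge_path = _best_edge_path(g, node_path, required)
        n_req = sum(1 for _, l, _ in edge_path if l in required)
        n_inst = sum(
            1 for (u, l, v) in edge_path
            if g.get_edge_data(u, v)[l].get("instantiated", True)
        )
        return (-n_req, -n_inst, node_path)
    return sorted(paths, key=key)


def discover_lca(
    elements,
    properties,
    ag: AcyclicGraph,
    table: LcaTable,
) -> SemanticAssociation:
    """Method 1: hub via the LCA table, then shortest hub->element paths.

    Among equal-length paths, those covering required properties are
    preferred, then those with more instantiated edges, then the
    lexicographically first.  A required property on no chosen path is
    dropped with a warning.
    """
    table.check(ag)
    g = ag.graph
    required = set(properties or [])
    hub = multi_lca(elements, table)
    paths = {}
    for el in sorted(set(elements)):
        if el == hub:
            paths[el] = []
            continue
        try:
            node_paths = list(itertools.islice(nx.all_shortest_paths(g, hub, el), 200))
        except nx.NetworkXNoPath:
            raise NoAssociationError(f"hub {hub} cannot reach element {el}")
        best = _rank_paths(g, node_paths, required)[0]
        paths[el] = _best_edge_path(g, best, required)
    included = sorted({l for p in paths.values() for _, l, _ in p if l in required})
    for prop in sorted(required - set(included)):
        logger.warning("required property %s lies on no selected path; dropped", prop)
    return SemanticAssociation(hub, paths, included)


def discover_paths(
    elements,
    ag: AcyclicGraph,
    max_paths: int = 25,
    max_len: int = 10,
    max_combinations: int = 20000,
) -> SemanticAssociation:
    """Method 2: pairwise path enumeration and intersection.

    Undirected simple paths (<= max_paths per pair, length <= max_len)
    are enumerated per element pair and sorted ascending by length; the
    Cartesian product of the per-pair path sets is scanned and the nodes
    common to every path of a combination are pooled into CommonNodes.
    The common node with the shortest paths to all the elements wins
    (directed reachability preferred, then total distance, then depth,
    then name).
    """
    elements = sorted(set(elements))
    if len(elements) < 2:
        raise ValueError("discover_paths needs at least two elements")
    g = ag.graph
    simple = nx.DiGraph(g)  # collapse parallel edges for path enumeration
    und = nx.Graph(simple.to_undirected(as_view=False))

    all_pairwise = []
    for x, y in itertools.combinations(elements, 2):
        try:
            paths = list(itertools.islice(
                nx.shortest_simple_paths(und, x, y), max_paths
            ))
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            raise NoAssociationError(f"no path between {x} and {y}")
        paths = [p for p in paths if len(p) - 1 <= max_len]
        if not paths:
            raise NoAssociationError(f"no path of length <= {max_len} between {x} and {y}")
        all_pairwise.append(sorted(paths, key=lambda p: (len(p), p)))

    common_nodes = set()
    for combo in itertools.islice(itertools.product(*all_pairwise), max_combinations):
        common = set(combo[0])
        for path in combo[1:]:
            common &= set(path)
        common_nodes |= common
    if not common_nodes:
        raise NoAssociationError(f"no common node across pairwise paths of {elements}")

    # prefer candidates that reach every element along directed edges
    depth = {n: 0 for n in g.nodes}
    for r in (n for n in sorted(g.nodes) if g.in_degree(n) == 0):
        for n, d in nx.single_source_shortest_path_length(g, r).items():
            depth[n] = max(depth[n], d)

    def directed_cost(c):
        total = 0
        for el in elements:
            if c == el:
                continue
            try:
                total += nx.shortest_path_length(g, c, el)
            except nx.NetworkXNoPath:
                return None
        return total

    scored = []
    for c in sorted(common_nodes):
        cost = directed_cost(c)
        if cost is not None:
            scored.append((0, cost, -depth.get(c, 0), c))
        else:
            total = sum(
                nx.shortest_path_length(und, c, el) for el in elements if el != c
            )
            scored.append((1, total, -depth.get(c, 0), c))
    scored.sort()
    hub = scored[0][3]

    paths = {}
    for el in elements:
        if el == hub:
            paths[el] = []
        elif nx.has_path(g, hub, el):
            node_path = nx.shortest_path(g, hub, el)
            paths[el] = _best_edge_path(g, node_path, set())
        else:
            node_path = nx.shortest_path(und, hub, el)
            edges = []
            for u, v in zip(node_path, node_path[1:]):
                if g.has_edge(u, v):
                    edges.append(_best_edge_path(g, [u, v], set())[0])
                else:
                    w, lbl, x = _best_edge_path(g, [v, u], set())[0]
                    edges.append((w, lbl, x))  # original orientation preserved
            paths[el] = edges
    return SemanticAssociation(hub, paths, [])


# -- triple generation ----------------------------------------------------

@dataclass
class TripleSequence:
    """Ordered RDF triples with a class -> variable table and numeric
    filter bindings; compiles to a SPARQL SELECT downstream."""

    triples: list  # (subj_var, predicate_iri, obj_var)
    var_classes: dict  # var -> class iri (typing constraint)
    filters: list = field(default_factory=list)  # (var, operator, numeric value)
    literal_filters: list = field(default_factory=list)  # (var, exact text)
    flags: list = field(default_factory=list)


def to_triples(
    assoc: SemanticAssociation,
    comparatives: list | None = None,
    split_map: dict | None = None,
    model: OntologyModel | None = None,
    comparative_elements: dict | None = None,
    instance_literals: dict | None = None,
) -> TripleSequence:
    """Compile a semantic association into an RDF triple sequence.

    Property edges become (?u, p, ?v) patterns with one stable variable
    per original class (?v0, ?v1, ... in class-sorted order); subclass
    edges refine the variable's type to the child class instead of
    emitting a pattern.  Split nodes are projected through ``split_map``
    first, so no split identifier survives.  Each comparative relation is
    bound to the datatype property of its matched element
    (``comparative_elements``: operand text -> class; unlisted operands
    are resolved against the association's classes by name similarity)
    and attached as a literal-constrained object with a filter.
    """
    split_map = split_map or {}

    def proj(node: str) -> str:
        return split_map.get(node, node)

    # walk paths: collect property edges between projected classes and
    # the most specific class seen per variable chain
    class_edges = []  # (subj_class, pred, obj_class)
    refined: dict[str, str] = {}  # class -> refined (deeper) class alias
    seen_classes = []

    def canon(cls: str) -> str:
        while cls in refined:
            cls = refined[cls]
        return cls

    for el in sorted(assoc.paths):
        for u, label, v in assoc.paths[el]:
            cu, cv = proj(u), proj(v)
            if label == SUBCLASS:
                # same instance variable, more specific type
                if canon(cu) != cv:
                    refined[canon(cu)] = cv
            else:
                class_edges.append((canon(cu), label, cv))
            for c in (cu, cv):
                if c not in seen_classes:
                    seen_classes.append(c)
    class_edges = [(canon(s), p, canon(o)) for s, p, o in class_edges]
    hub_class = canon(proj(assoc.hub))

    classes = sorted({hub_class} | {s for s, _, _ in class_edges} | {o for _, _, o in class_edges})
    var_of = {c: f"?v{i}" for i, c in enumerate(classes)}
    triples = []
    for s, p, o in class_edges:
        t = (var_of[s], p, var_of[o])
        if t not in triples:
            triples.append(t)
    var_classes = {var_of[c]: c for c in classes}

    seq = TripleSequence(triples, var_classes)
    lit_count = 0
    lit_cache: dict[tuple, str] = {}  # (class var, predicate) -> literal var

    def literal_var(class_var: str, predicate: str) -> str:
        nonlocal lit_count
        key = (class_var, predicate)
        if key not in lit_cache:
            lit_cache[key] = f"?lit{lit_count}"
            lit_count += 1
            triples.append((class_var, predicate, lit_cache[key]))
        return lit_cache[key]

    comparative_elements = comparative_elements or {}
    for rel in comparatives or []:
        target = comparative_elements.get(rel.operand)
        if target is None and model is not None:
            best, best_score = None, 0.0
            for c in classes:
                s = similarity(rel.operand, model.name_of(c), "isub")
                if s > best_score:
                    best, best_score = c, s
            if best_score >= 0.5:
                target = best
        target = canon(target) if target else None
        if target is None or target not in var_of:
            raise UnboundFilterError(
                f"comparative operand {rel.operand!r} has no matched element"
            )
        dt_prop = _datatype_property_for(model, target) if model else None
        if dt_prop is None:
            raise UnboundFilterError(
                f"no datatype property found for class {target} (operand {rel.operand!r})"
            )
        seq.filters.append((literal_var(var_of[target], dt_prop), rel.operator, rel.value))

    # instance-matched entities constrain their class variable's label
    for cls, text in sorted((instance_literals or {}).items()):
        cls = canon(proj(cls))
        if cls in var_of:
            lv = literal_var(var_of[cls], "http://www.w3.org/2000/01/rdf-schema#label")
            seq.literal_filters.append((lv, text))
    return seq


def _datatype_property_for(model: OntologyModel, cls: str) -> str | None:
    """The (lexicographically first) numeric-range datatype property whose
    domain covers cls or one of its ancestors."""
    ancestors = {cls}
    frontier = [cls]
    while frontier:
        node = frontier.pop()
        for p in model.parents_of(node):
            if p not in ancestors:
                ancestors.add(p)
                frontier.append(p)
    cands = sorted(
        iri for iri, prop in model.properties.items()
        if prop.kind == "datatype" and prop.domains & ancestors
    )
    return cands[0] if cands else None
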