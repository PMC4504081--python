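"""SPARQL generation and execution.

A :class:`~ontoqa.association.TripleSequence` compiles to a SPARQL 1.1
SELECT: one basic graph pattern per triple, an rdf:type constraint per
class variable, and one FILTER per comparative binding (numeric
xsd:decimal cast).  Execution goes through an endpoint contract with two
implementations: an in-process rdflib store loaded from Turtle files,
and SPARQL-over-HTTP via the standard library.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.request
from dataclasses import dataclass, field

import networkx as nx
import rdflib
from rdflib.plugins.sparql import prepareQuery

from .association import TripleSequence

UNSUPPORTED_FLAGS = {"negation", "aggregate", "cross_class_comparison", "single_entity"}


class CompilationError(ValueError):
    pass


class UnsupportedQueryError(CompilationError):
    """The triple sequence needs query features the compiler refuses
    (negation, aggregates, nested/grouped queries)."""


class EndpointError(RuntimeError):
    """Transport failure; carries the query for retry."""

    def __init__(self, message: str, query: "SparqlQuery | None" = None):
        super().__init__(message)
        self.query = query


class ProtocolError(RuntimeError):
    """Malformed endpoint response or invalid query."""


@dataclass
class SparqlQuery:
    text: str
    variables: list
    provenance: dict = field(default_factory=dict)  # variable -> class iri


@dataclass
class AnswerTable:
    columns: list
    rows: list  # tuples of bound values (strings)

    def __post_init__(self):
        assert all(len(r) == len(self.columns) for r in self.rows)

    def as_sets(self):
        return set(map(tuple, self.rows))


def compile(triples: TripleSequence, targets: list | None = None) -> SparqlQuery:
    """Compile a triple sequence into a SELECT DISTINCT query.

    ``targets``: variables to project (the question's target entities);
    literal-valued variables are always projected too.  None projects
    every variable.  Raises :class:`CompilationError` on an empty or
    unchained sequence, :class:`UnsupportedQueryError` when the sequence
    is flagged as needing unsupported query features.
    """
    unsupported = set(triples.flags) & UNSUPPORTED_FLAGS
    if unsupported:
        raise UnsupportedQueryError(f"refusing query requiring: {sorted(unsupported)}")
    if not triples.triples:
        raise CompilationError("empty triple sequence")

    chain = nx.Graph()
    for s, _, o in triples.triples:
        chain.add_edge(s, o)
    for v in triples.var_classes:
        chain.add_node(v)
    if chain.number_of_nodes() and not nx.is_connected(chain):
        raise CompilationError("triple sequence is not chained")

    lit_vars = sorted(
        {o for _, _, o in triples.triples if o not in triples.var_classes}
        | {v for v, _, _ in triples.filters}
    )
    if targets:
        projected = [v for v in targets if v in chain] + lit_vars
    else:
        projected = sorted(triples.var_classes) + lit_vars
    projected = list(dict.fromkeys(projected))
    if not projected:
        raise CompilationError("no variables to project")

    lines = ["PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>",
             "PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>",
             f"SELECT DISTINCT {' '.join(projected)}",
             "WHERE {"]
    for v in sorted(triples.var_classes):
        lines.append(f"  {v} rdf:type <{triples.var_classes[v]}> .")
    for s, p, o in triples.triples:
        lines.append(f"  {s} <{p}> {o} .")
    for v, op, value in triples.filters:
        sparql_op = {"=": "=", "<": "<", ">": ">", "<=": "<=", ">=": ">="}[op]
        lines.append(f"  FILTER (xsd:decimal({v}) {sparql_op} {value})")
    for v, text in getattr(triples, "literal_filters", []):
        escaped = text.replace('"', '\\"').lower()
        lines.append(f'  FILTER (LCASE(STR({v})) = "{escaped}")')
    lines.append("}")
    text = "\n".join(lines)

    try:
        prepareQuery(text)
    except Exception as exc:
        raise CompilationError(f"generated query does not parse: {exc}") from exc
    return SparqlQuery(text, projected, dict(triples.var_classes))


class LocalEndpoint:
    """In-process endpoint over an rdflib graph (Turtle/N-Triples files)."""

    def __init__(self, source):
        if isinstance(source, rdflib.Graph):
            self.graph = source
        else:
            self.graph = rdflib.Graph()
            self.graph.parse(str(source))

    def select(self, text: str):
        try:
            result = self.graph.query(text)
        except Exception as exc:
            raise ProtocolError(f"query rejected: {exc}") from exc
        columns = [f"?{v}" for v in result.vars]
        rows = [tuple("" if b is None else str(b) for b in row) for row in result]
        return columns, rows


class HttpEndpoint:
    """SPARQL 1.1 protocol over HTTP (SELECT, sparql-results+json)."""

    def __init__(self, url: str, timeout: float = 30.0):
        self.url = url
        self.timeout = timeout

    def select(self, text: str):
        req = urllib.request.Request(
            self.url,
            data=text.encode(),
            headers={
                "Content-Type": "application/sparql-query",
                "Accept": "application/sparql-results+json",
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                payload = resp.read()
        except urllib.error.URLError as exc:
            raise EndpointError(f"endpoint unreachable: {exc}") from exc
        try:
            obj = json.loads(payload)
            columns = [f"?{v}" for v in obj["head"]["vars"]]
            rows = [
                tuple(b.get(v, {}).get("value", "") for v in obj["head"]["vars"])
                for b in obj["results"]["bindings"]
            ]
        except (KeyError, ValueError) as exc:
            raise ProtocolError(f"malformed SPARQL response: {exc}") from exc
        return columns, rows


def execute(q: SparqlQuery, endpoint) -> AnswerTable:
    """Run a compiled query; an empty result is a zero-row table."""
    try:
        columns, rows = endpoint.select(q.text)
    except EndpointError as exc:
        exc.query = q
        raise
    return AnswerTable(columns, rows)
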