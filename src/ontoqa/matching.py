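"""Refining recognized entities to specific ontology elements.

An entity carrying upper-level label c is matched against the elements of
S_c (the hierarchy rooted at c) by string similarity over their names,
rdfs:label strings and rdfs:comment n-grams.  Three cases follow from the
candidate list: a single candidate is retained directly; multiple
candidates are ranked by how many direct graph paths each has to the
other entities' elements (contextual consistency); an empty list falls
back to exact lexical matching against instances in the RDF data, taking
the instance's rdf:type class as the element.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import rdflib
from rdflib import RDF, RDFS

from .ontology import OntologyModel, local_name, subtree_elements
from .recognition import RecognizedEntity
from .similarity import MEASURES, similarity

logger = logging.getLogger(__name__)

DEFAULT_MEASURE = "isub"
DEFAULT_THRESHOLD = 0.6
THRESHOLD_SWEEP = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class MatchCandidate:
    element: str
    score: float
    matched_field: str  # name | label | comment | instance
    context_rank: int = 0


@dataclass
class MatchedEntity:
    entity: RecognizedEntity
    element: str | None
    provenance: str  # single | context_ranked | instance | unmatched
    alternatives: list = field(default_factory=list)


def _comment_fragments(comment: str, n_max: int = 3) -> list:
    toks = comment.split()
    frags = []
    for n in range(1, n_max + 1):
        frags += [" ".join(toks[i : i + n]) for i in range(len(toks) - n + 1)]
    return frags


def element_score(text: str, element: str, model: OntologyModel, measure: str):
    """Max similarity of text against the element's name, label and
    comment fragments; returns (score, field)."""
    best = (similarity(text, model.name_of(element), measure), "name")
    label = model.label_of(element)
    if label:
        s = similarity(text, label, measure)
        if s > best[0]:
            best = (s, "label")
    comment = model.comment_of(element)
    if comment:
        for frag in _comment_fragments(comment):
            s = similarity(text, frag, measure)
            if s > best[0]:
                best = (s, "comment")
    return best


def schema_candidates(
    text: str,
    label: str,
    model: OntologyModel,
    measure: str = DEFAULT_MEASURE,
    threshold: float = DEFAULT_THRESHOLD,
) -> list:
    cands = []
    for el in sorted(subtree_elements(model, label)):
        score, fld = element_score(text, el, model, measure)
        if score >= threshold:
            cands.append(MatchCandidate(el, score, fld))
    return sorted(cands, key=lambda c: (-c.score, c.element))


def _direct_paths(graph: nx.MultiDiGraph, a: str, b: str, max_len: int = 3) -> int:
    """Number of undirected simple paths of length <= max_len between a and b."""
    if a not in graph or b not in graph or a == b:
        return 0
    und = nx.Graph(graph.to_undirected(as_view=False))
    try:
        return sum(1 for _ in nx.all_simple_paths(und, a, b, cutoff=max_len))
    except nx.NodeNotFound:
        return 0


def instance_classes(text: str, data: rdflib.Graph) -> list:
    """Classes typing instances whose literal values or IRI local names
    exactly (case-insensitively) match the entity text."""
    needle = text.strip().lower()
    hits = set()
    for s, _, o in data.triples((None, None, None)):
        if isinstance(o, rdflib.Literal) and str(o).strip().lower() == needle:
            hits.add(s)
    for s in set(data.subjects(RDF.type, None)):
        if isinstance(s, rdflib.URIRef) and local_name(str(s)).lower() == needle:
            hits.add(s)
    classes = set()
    for inst in hits:
        for cls in data.objects(inst, RDF.type):
            if isinstance(cls, rdflib.URIRef):
                classes.add(str(cls))
    return sorted(classes)


def match_entity(
    entity: RecognizedEntity,
    model: OntologyModel,
    graph: nx.MultiDiGraph | None = None,
    data: rdflib.Graph | None = None,
    measure: str = DEFAULT_MEASURE,
    threshold: float = DEFAULT_THRESHOLD,
    context: list | None = None,
) -> MatchedEntity:
    """Resolve an entity to a specific ontology element (cases 1-3).

    ``context`` carries the other entities' already-resolved elements
    (upper-level labels as fallback) for the case-2 direct-path ranking.
    """
    cands = schema_candidates(entity.text, entity.label, model, measure, threshold)
    if len(cands) == 1:
        return MatchedEntity(entity, cands[0].element, "single", cands)
    if len(cands) > 1:
        ranked = _rank_by_context(cands, graph, context, model)
        return MatchedEntity(entity, ranked[0].element, "context_ranked", ranked)
    # case 3: instance matching
    if data is not None:
        classes = instance_classes(entity.text, data)
        if len(classes) == 1:
            return MatchedEntity(entity, classes[0], "instance",
                                 [MatchCandidate(classes[0], 1.0, "instance")])
        if len(classes) > 1:
            cands = [MatchCandidate(c, 1.0, "instance") for c in classes]
            ranked = _rank_by_context(cands, graph, context, model)
            return MatchedEntity(entity, ranked[0].element, "instance", ranked)
    logger.warning("entity %r (label %s) unmatched", entity.text, entity.label)
    return MatchedEntity(entity, None, "unmatched", [])


def _rank_by_context(cands, graph, context, model):
    if graph is None or not context:
        return sorted(cands, key=lambda c: (-c.score, c.element))
    scored = []
    for c in cands:
        n = sum(_direct_paths(graph, c.element, other) for other in context if other)
        scored.append((c, n))
    scored.sort(key=lambda cn: (-cn[1], -cn[0].score, cn[0].element))
    return [
        MatchCandidate(c.element, c.score, c.matched_field, n) for c, n in scored
    ]


# -- evaluation -----------------------------------------------------------

def evaluate_matching(gold: list, predictions: list) -> dict:
    """Precision / recall / rejection / F1 of element matching.

    ``gold``: per-entity correct element, or None when the entity has no
    correct match (a true dissimilar).  ``predictions``: the matched
    element or None (rejected).  Precision is correct matches over all
    matches, recall correct matches over all entities with a correct
    element, rejection correctly-rejected dissimilars over all truly
    dissimilar entities (so raising the threshold can only improve it,
    mirroring the recall trade-off).  Zero denominators are reported as
    0 with a flag.
    """
    if not gold:
        raise ValueError("gold set is empty")
    assert len(gold) == len(predictions)
    matched = [(g, p) for g, p in zip(gold, predictions) if p is not None]
    correct = sum(1 for g, p in matched if g == p)
    n_correct_labels = sum(1 for g in gold if g is not None)
    dissimilar = [(g, p) for g, p in zip(gold, predictions) if g is None]
    correct_dissimilar = sum(1 for g, p in dissimilar if p is None)

    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    precision = ratio(correct, len(matched), "precision")
    recall = ratio(correct, n_correct_labels, "recall")
    rejection = ratio(correct_dissimilar, len(dissimilar), "rejection")
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "rejection": rejection,
            "f1": f1, "zero_denominator": flags}


def match_string(text: str, elements: list, model: OntologyModel,
                 measure: str, threshold: float) -> str | None:
    """Dictionary-style matcher used by the threshold sweep: the best
    element at or above the threshold, else None."""
    best, best_score = None, 0.0
    for el in elements:
        score, _ = element_score(text, el, model, measure)
        if score > best_score or (score == best_score and best and el < best):
            best, best_score = el, score
    return best if best_score >= threshold else None


def sweep(
    gold_pairs: list,
    model: OntologyModel,
    elements: list | None = None,
    measures=MEASURES,
    thresholds=THRESHOLD_SWEEP,
) -> list:
    """Measure x threshold grid of matching metrics.

    ``gold_pairs``: (entity text, correct element or None).  Returns rows
    of dicts with measure, threshold and the four metrics.
    """
    elements = sorted(model.elements()) if elements is None else elements
    rows = []
    for measure in measures:
        # score once per measure, threshold applied afterwards
        scored = []
        for text, gold_el in gold_pairs:
            best, best_score = None, 0.0
            for el in elements:
                s, _ = element_score(text, el, model, measure)
                if s > best_score:
                    best, best_score = el, s
            scored.append((gold_el, best, best_score))
        for th in thresholds:
            preds = [b if s >= th else None for _, b, s in scored]
            metrics = evaluate_matching([g for g, _, _ in scored], preds)
            rows.append({"measure": measure, "threshold": th, **metrics})
    return rows


def sweep_to_tsv(rows: list) -> str:
    header = "measure\tthreshold\tprecision\trecall\trejection\tf1"
    lines = [header] + [
        f"{r['measure']}\t{r['threshold']}\t{r['precision']:.4f}\t{r['recall']:.4f}"
        f"\t{r['rejection']:.4f}\t{r['f1']:.4f}"
        for r in rows
    ]
    return "\n".join(lines)
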