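"""End-to-end orchestration: question in, answer table out.

``Pipeline.answer`` runs preprocess -> recognize -> match -> associate ->
compile -> execute, capturing every stage's output even when a later
stage fails, and refusing question types the method cannot answer
(negation, aggregates, cross-class arithmetic comparisons, single-entity
questions).  Per-stage *corrections* can replace the recognized
entities, the matched elements, or the triple sequence, modeling the
user-intervention scenarios of the system evaluation.
"""

from __future__ import annotations

import random
import time
from dataclasses import dataclass, field

from . import association as assoc_mod
from . import matching, recognition, sparql
from .association import LcaTable, NoAssociationError, UnboundFilterError
from .ontology import AcyclicGraph, OntologyModel
from .preprocess import preprocess
from .similarity import similarity


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    measure: str = "isub"
    threshold: float = 0.6
    method: str = "lca"  # lca | paths
    dict_sim_threshold: float = 0.6
    seed: int = 7


@dataclass
class QuestionResult:
    question: str
    processed: object = None
    entities: list | None = None
    matches: list | None = None
    association: object = None
    triples: object = None
    sparql_query: object = None
    answers: object = None
    refusal_reason: str | None = None
    failure_stage: str | None = None
    failure_detail: str | None = None
    timings: dict = field(default_factory=dict)

    @property
    def answered(self) -> bool:
        return self.answers is not None

    @property
    def refused(self) -> bool:
        return self.refusal_reason is not None


class Pipeline:
    """The assembled question-answering system over one ontology + store."""

    def __init__(
        self,
        model: OntologyModel,
        graph,
        dag: AcyclicGraph,
        table: LcaTable,
        crf,
        endpoint,
        data=None,
        cfg: PipelineConfig | None = None,
    ):
        self.model = model
        self.graph = graph
        self.dag = dag
        self.table = table
        self.crf = crf
        self.endpoint = endpoint
        self.data = data
        self.cfg = cfg or PipelineConfig()
        self._upper_of = recognition.upper_ancestor_map(model)

    # -- single question ---------------------------------------------------

    def answer(self, question: str, corrections: dict | None = None) -> QuestionResult:
        corrections = corrections or {}
        result = QuestionResult(question)
        t0 = time.perf_counter()

        def clock(stage):
            nonlocal t0
            t1 = time.perf_counter()
            result.timings[stage] = t1 - t0
            t0 = t1

        # 1. linguistic pre-processing
        try:
            q = preprocess(question)
        except Exception as exc:
            result.failure_stage, result.failure_detail = "preprocess", str(exc)
            return result
        result.processed = q
        clock("preprocess")
        unsupported = [f for f in q.flags if f in ("negation", "aggregate",
                                                   "cross_class_comparison")]
        if unsupported:
            result.refusal_reason = unsupported[0]
            return result

        # 2. entity recognition
        if "entities" in corrections:
            entities = list(corrections["entities"])
        else:
            entities = recognition.recognize(
                q, self.crf, self.model, self.cfg.dict_sim_threshold, self._upper_of
            )
        result.entities = entities
        clock("recognize")
        if not entities:
            result.failure_stage = "recognize"
            result.failure_detail = "no entities recognized"
            return result

        # 3. ontology element matching
        if "elements" in corrections:
            gold = corrections["elements"]
            matches = []
            for e in entities:
                el = gold.get(e.text)
                prov = "corrected"
                if el is not None:
                    score, _ = matching.element_score(e.text, el, self.model,
                                                      self.cfg.measure)
                    # a corrected element the surface does not lexically
                    # match behaves like an instance match downstream
                    if score < self.cfg.threshold:
                        prov = "instance"
                matches.append(matching.MatchedEntity(e, el, prov, []))
        else:
            matches = self._match_all(entities)
        result.matches = matches
        clock("match")

        resolved = [m for m in matches if m.element is not None]
        classes = sorted({m.element for m in resolved
                          if m.element in self.model.classes})
        properties = sorted({m.element for m in resolved
                             if m.element in self.model.properties})

        if "triples" in corrections:
            result.triples = corrections["triples"]
            target_vars = [corrections["target_var"]] if corrections.get("target_var") else None
        else:
            if len(classes) < 2:
                result.refusal_reason = "single_entity"
                return result
            # 4. semantic association discovery
            try:
                if self.cfg.method == "paths":
                    assoc = assoc_mod.discover_paths(classes, self.dag)
                else:
                    assoc = assoc_mod.discover_lca(classes, properties,
                                                   self.dag, self.table)
            except NoAssociationError as exc:
                result.failure_stage, result.failure_detail = "associate", str(exc)
                return result
            result.association = assoc
            clock("associate")

            # 5. triple generation
            comparative_elements = self._bind_operands(q.comparatives, matches)
            instance_literals = {
                m.element: m.entity.text for m in resolved
                if m.provenance == "instance"
            }
            try:
                result.triples = assoc_mod.to_triples(
                    assoc, q.comparatives, self.dag.split_map, self.model,
                    comparative_elements, instance_literals,
                )
            except UnboundFilterError as exc:
                result.failure_stage, result.failure_detail = "triples", str(exc)
                return result
            target_vars = self._target_vars(q, matches, result.triples)
        clock("triples")

        # 6. query formulation and answer retrieval
        try:
            query = sparql.compile(result.triples, target_vars)
        except sparql.CompilationError as exc:
            result.failure_stage, result.failure_detail = "compile", str(exc)
            return result
        result.sparql_query = query
        try:
            result.answers = sparql.execute(query, self.endpoint)
        except (sparql.EndpointError, sparql.ProtocolError) as exc:
            result.failure_stage, result.failure_detail = "execute", str(exc)
            return result
        clock("execute")
        return result

    # -- helpers -----------------------------------------------------------

    def _match_all(self, entities):
        matches = []
        # context for case-2 ranking: other entities' upper labels first,
        # replaced by resolved elements as they become available
        context_elements = {e: self.model.resolve_upper(e.label) for e in entities}
        for e in entities:
            ctx = [v for k, v in context_elements.items() if k is not e and v]
            m = matching.match_entity(
                e, self.model, self.graph, self.data,
                self.cfg.measure, self.cfg.threshold, ctx,
            )
            if m.element:
                context_elements[e] = m.element
            matches.append(m)
        return matches

    def _bind_operands(self, comparatives, matches):
        bound = {}
        for rel in comparatives:
            best, best_score = None, 0.0
            for m in matches:
                if m.element is None:
                    continue
                s = 1.0 if m.entity.text.casefold() == rel.operand.casefold() \
                    else similarity(rel.operand, m.entity.text, "isub")
                if s > best_score:
                    best, best_score = m.element, s
            if best is not None and best_score >= 0.5:
                bound[rel.operand] = best
        return bound

    def _target_vars(self, q, matches, triples):
        """Variables of entities before the question's first verb; when the
        question opens with the verb, the first recognized entity."""
        first_vb = next((i for i, t in enumerate(q.pos_tags) if t == "VB"),
                        len(q.tokens))
        targets = [m for m in matches
                   if m.element and m.entity.start < first_vb]
        if not targets:
            targets = [m for m in matches if m.element][:1]
        var_by_class = {c: v for v, c in triples.var_classes.items()}
        out = [var_by_class[m.element] for m in targets
               if m.element in var_by_class]
        return out or None


# -- full-system evaluation ------------------------------------------------

def evaluate_system(
    questions: list,
    model: OntologyModel,
    graph,
    dag: AcyclicGraph,
    table: LcaTable,
    endpoint,
    data=None,
    k: int = 2,
    seed: int = 7,
    cfg: PipelineConfig | None = None,
    scenarios=(1, 2, 3, 4),
) -> dict:
    """Four-scenario evaluation with k-fold retraining of the recognizer.

    ``questions`` are corpus items carrying gold layers (entities,
    elements, triples + target variable, answer rows).  Scenario 1 runs
    the pipeline untouched; scenario 2 injects gold entities; scenario 3
    gold entities and elements; scenario 4 gold triple sequences.
    Precision is the proportion of questions generating a correct answer
    among those generating any; recall the proportion of gold-answerable
    questions answered correctly.
    """
    if not questions:
        raise ConfigError("empty corpus")
    evaluable = [q for q in questions if q.triples is not None and q.answers is not None]
    if not evaluable:
        raise ConfigError("gold layer missing: no question has gold triples and answers")
    if k < 2 or k > len(questions):
        raise ConfigError(f"k={k} incompatible with corpus size {len(questions)}")

    rng = random.Random(seed)
    order = list(range(len(questions)))
    rng.shuffle(order)
    folds = [order[i::k] for i in range(k)]

    per_scenario = {s: {"correct": 0, "produced": 0, "total": 0} for s in scenarios}
    for f in range(k):
        test_idx = set(folds[f])
        train_items = [(questions[i].tokens, questions[i].labels)
                       for i in order if i not in test_idx]
        crf = recognition.train(recognition.TrainingCorpus(train_items),
                                seed=seed, model=model)
        pipe = Pipeline(model, graph, dag, table, crf, endpoint, data, cfg)
        for i in sorted(test_idx):
            q = questions[i]
            if q.triples is None or q.answers is None:
                continue
            for s in scenarios:
                corrections = {}
                if s >= 2:
                    corrections["entities"] = q.entities
                if s >= 3:
                    corrections["elements"] = q.elements
                if s >= 4:
                    corrections["triples"] = q.triples
                    corrections["target_var"] = q.target_var
                res = pipe.answer(q.question, corrections)
                stats = per_scenario[s]
                stats["total"] += 1
                if res.answers is not None or res.sparql_query is not None:
                    stats["produced"] += 1
                    if res.answers is not None and \
                            res.answers.as_sets() == set(map(tuple, q.answers)):
                        stats["correct"] += 1

    out = {}
    for s, st in per_scenario.items():
        p = st["correct"] / st["produced"] if st["produced"] else 0.0
        r = st["correct"] / st["total"] if st["total"] else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        out[f"scenario_{s}"] = {"precision": p, "recall": r, "f1": f1, **st}
    return out
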