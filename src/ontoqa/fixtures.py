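"""Synthetic ontology, instance data and labeled question corpus.

The generator emulates the shape of a provenance ontology for parasite
experimentation: a class/subclass hierarchy under eight upper-level
branches (process, data collection, agent, parameter, material,
instrument, justification, pathway element), object properties linking
processes to their outputs and materials to their measurements, a few
property edges that close cycles, and typed instance data with numeric
measurement values.  Embedded in the hierarchy are three worked
subgraph topologies: a chain whose lowest common ancestor is *cell
cloning*; a fork whose hub is *proteome analysis*; and four sibling
branches whose elements reduce to the hub *process*.  A fourth pattern,
``parameter --transformation of--> data collection``, closes a cycle
that the DAG transformation must break by splitting.

The question corpus is templated: entity slots are filled with ontology
vocabulary (optionally near-miss or abbreviated surfaces), token-level
gold labels follow the slot's upper-level branch, and for satisfiable
patterns the gold triple sequence and gold answer rows are computed by
direct scans of the instance data, independent of the pipeline.

Everything is deterministic given the spec's seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import rdflib
from rdflib import OWL, RDF, RDFS, XSD, Literal, Namespace, URIRef

from .association import TripleSequence
from .preprocess import ComparativeRelation, tokenize
from .recognition import OUTSIDE, RecognizedEntity, TrainingCorpus

ONT = Namespace("http://example.org/onto#")
DAT = Namespace("http://example.org/data#")

UPPER_LABELS = (
    "process", "data collection", "agent", "parameter",
    "material", "instrument", "justification", "pathway element",
)


class FixtureConfigError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Generation parameters; defaults are the package's study conditions."""

    seed: int = 7
    n_classes: int = 40
    hierarchy_depth: int = 4
    branching: int = 3
    n_object_properties: int = 18
    cycle_count: int = 3
    n_instances: int = 12
    corpus_size: int = 200
    template_mix: dict = field(default_factory=lambda: {
        "no_comparative": 0.35, "one_comparative": 0.45, "two_comparative": 0.20,
    })
    p_abbreviation: float = 0.15
    p_instance_entity: float = 0.10
    p_near_miss: float = 0.20
    labels: tuple = UPPER_LABELS

    def validate(self):
        for name in ("n_classes", "n_object_properties", "cycle_count",
                     "n_instances", "corpus_size"):
            if getattr(self, name) < 0:
                raise FixtureConfigError(f"{name} must be >= 0")
        if abs(sum(self.template_mix.values()) - 1.0) > 1e-9:
            raise FixtureConfigError("template_mix fractions must sum to 1")
        if self.cycle_count > self.n_object_properties:
            raise FixtureConfigError("cycle_count exceeds the number of object properties")


def iri(name: str) -> str:
    return str(ONT[name.replace(" ", "_")])


# (child, parent) subclass axioms of the hand-wired core hierarchy
_CORE_SUBCLASSES = [
    # upper branches under the root
    *[(u, "entity") for u in UPPER_LABELS],
    # process branch: chain (cell cloning hub) and fork (proteome analysis hub)
    ("cell cloning", "process"), ("proteome analysis", "process"),
    ("pathway analysis", "process"), ("microarray analysis", "process"),
    ("sequence extraction", "process"),
    ("drug selection", "cell cloning"), ("transfection", "drug selection"),
    ("strain creation", "transfection"),
    ("protein identification", "proteome analysis"),
    ("sample sequencing", "proteome analysis"),
    # data collection branch
    ("spectral count", "data collection"), ("log2 ratio", "data collection"),
    ("five prime forward region", "data collection"),
    ("peptide count", "data collection"), ("drug resistance", "data collection"),
    # agent / parameter / material / instrument / justification / pathway
    ("researcher", "agent"), ("organization", "agent"),
    ("gene function", "parameter"), ("drug concentration", "parameter"),
    ("biological material", "material"), ("organism", "material"),
    ("gene", "biological material"), ("protein", "biological material"),
    ("plasmid", "biological material"),
    ("mass spectrometer", "instrument"), ("microarray chip", "instrument"),
    ("experiment justification", "justification"),
    ("hypothesis statement", "justification"),
    ("pathway", "pathway element"), ("metabolic pathway", "pathway"),
]

# object properties: (name, domain, range); the last three close cycles
_CORE_OBJECT_PROPERTIES = [
    ("produces count", "protein identification", "spectral count"),
    ("produces ratio", "microarray analysis", "log2 ratio"),
    ("describes region", "sample sequencing", "five prime forward region"),
    ("modifies", "strain creation", "gene"),
    ("has measurement", "gene", "spectral count"),
    ("has expression", "gene", "log2 ratio"),
    ("participates in", "gene", "pathway"),
    ("annotated with", "gene", "gene function"),
    ("has agent", "sequence extraction", "researcher"),
    ("has output value", "sequence extraction", "drug resistance"),
    ("uses instrument", "protein identification", "mass spectrometer"),
    ("has parameter", "data collection", "parameter"),
    ("involves", "pathway", "protein"),
    ("has justification", "cell cloning", "experiment justification"),
    ("analyzes", "pathway analysis", "pathway"),
    ("supports", "experiment justification", "hypothesis statement"),
]
_CYCLE_PROPERTIES = [
    ("transformation of", "parameter", "data collection"),
    ("refined into", "hypothesis statement", "experiment justification"),
    ("member of", "protein", "pathway"),
]

_DATATYPE_PROPERTIES = [
    ("has value", ("spectral count", "log2 ratio", "peptide count",
                   "drug resistance", "drug concentration"), XSD.decimal),
    ("has name", ("pathway", "gene", "researcher"), XSD.string),
    ("has identifier", ("gene",), XSD.string),
    ("has note", ("experiment justification",), XSD.string),
]

_COMMENTS = {
    "spectral count": "number of peptide spectra observed for a protein, also called spectra score",
    "log2 ratio": "log2 transcript abundance ratio between life cycle stages",
    "five prime forward region": "five prime forward sequence region of a gene",
    "drug resistance": "resistance outcome such as Neomycin resistance observed after drug selection",
    "gene function": "functional annotation assigned to a gene product",
    "pathway": "metabolic pathway membership for annotated genes",
    "gene": "annotated gene of the studied organism",
    "researcher": "scientist performing or supervising an experiment step",
}

#: curated near-miss surfaces that still resolve to the right element
_ALIASES = {
    "spectral count": ["spectra score", "spectral counts"],
    "log2 ratio": ["log2 ratios"],
    "gene": ["genes"],
    "researcher": ["researchers"],
    "pathway": ["pathways"],
    "peptide count": ["peptide counts"],
    "drug resistance": ["Neomycin resistance"],
}


@dataclass
class Fixture:
    """Generated ontology + data + gold structures."""

    spec: FixtureSpec
    ontology: rdflib.Graph
    data: rdflib.Graph
    subtree_gold: dict  # upper label name -> set of class names under it
    class_names: list
    property_names: list
    gf_literals: list  # gene-function instance label texts


def _build_class_lists(spec: FixtureSpec):
    subclasses = list(_CORE_SUBCLASSES)
    classes = ["entity"] + sorted({c for c, _ in subclasses})
    rng = random.Random(f"{spec.seed}-classes")
    extra = max(0, spec.n_classes - len(classes))
    aux = []
    for i in range(extra):
        name = f"auxiliary concept {i + 1}"
        parent = rng.choice(UPPER_LABELS)
        subclasses.append((name, parent))
        classes.append(name)
        aux.append(name)
    return classes, subclasses, aux


def _build_property_lists(spec: FixtureSpec, aux: list):
    props = list(_CORE_OBJECT_PROPERTIES) + _CYCLE_PROPERTIES[: spec.cycle_count]
    for k in range(3, spec.cycle_count):
        props.append((f"reverts {k - 2}", "strain creation", "cell cloning"))
    extra = max(0, spec.n_object_properties - len(props))
    for k in range(extra):
        if len(aux) >= 2:
            props.append((f"relates to {k + 1}", aux[k % (len(aux) - 1)], aux[-1]))
    return props


def generate_ontology(spec: FixtureSpec) -> Fixture:
    """Build the ontology and instance-data graphs plus gold subtree map."""
    spec.validate()
    classes, subclasses, aux = _build_class_lists(spec)
    obj_props = _build_property_lists(spec, aux)

    g = rdflib.Graph()
    g.bind("onto", ONT)
    for name in classes:
        ref = URIRef(iri(name))
        g.add((ref, RDF.type, OWL.Class))
        g.add((ref, RDFS.label, Literal(name)))
        if name in _COMMENTS:
            g.add((ref, RDFS.comment, Literal(_COMMENTS[name])))
    for child, parent in subclasses:
        g.add((URIRef(iri(child)), RDFS.subClassOf, URIRef(iri(parent))))
    for name, dom, rng_ in obj_props:
        ref = URIRef(iri(name))
        g.add((ref, RDF.type, OWL.ObjectProperty))
        g.add((ref, RDFS.label, Literal(name)))
        g.add((ref, RDFS.domain, URIRef(iri(dom))))
        g.add((ref, RDFS.range, URIRef(iri(rng_))))
    for name, domains, xsd_range in _DATATYPE_PROPERTIES:
        ref = URIRef(iri(name))
        g.add((ref, RDF.type, OWL.DatatypeProperty))
        g.add((ref, RDFS.label, Literal(name)))
        for d in domains:
            g.add((ref, RDFS.domain, URIRef(iri(d))))
        g.add((ref, RDFS.range, xsd_range))

    data, gf_literals = _generate_data(spec)

    subtree_gold = {}
    children = {}
    for child, parent in subclasses:
        children.setdefault(parent, []).append(child)
    for upper in spec.labels:
        seen = {upper}
        frontier = [upper]
        while frontier:
            node = frontier.pop()
            for ch in children.get(node, []):
                if ch not in seen:
                    seen.add(ch)
                    frontier.append(ch)
        subtree_gold[upper] = seen

    return Fixture(spec, g, data, subtree_gold, classes,
                   [p[0] for p in obj_props] + [p[0] for p in _DATATYPE_PROPERTIES],
                   gf_literals)


def _generate_data(spec: FixtureSpec):
    rng = random.Random(f"{spec.seed}-data")
    d = rdflib.Graph()
    d.bind("dat", DAT)
    d.bind("onto", ONT)

    def typed(local: str, cls: str) -> URIRef:
        ref = DAT[local]
        d.add((ref, RDF.type, URIRef(iri(cls))))
        return ref

    pathways = []
    for i, name in enumerate(["glycolysis", "citrate cycle", "purine metabolism",
                              "fatty acid synthesis"]):
        p = typed(f"pathway_{i + 1}", "pathway")
        d.add((p, URIRef(iri("has name")), Literal(name)))
        pathways.append(p)

    gf_literals = ["protein phosphate", "kinase activity", "membrane transporter"]
    gfs = []
    for i, text in enumerate(gf_literals):
        gf = typed(f"gene_function_{i + 1}", "gene function")
        d.add((gf, RDFS.label, Literal(text)))
        gfs.append(gf)

    for i in range(spec.n_instances):
        gene = typed(f"gene_{i + 1}", "gene")
        d.add((gene, URIRef(iri("has identifier")),
               Literal(f"Tc00.10470535{9463 + i}.{10 + i}")))
        for j in range(rng.randint(1, 2)):
            sc = typed(f"spectral_count_{i + 1}_{j + 1}", "spectral count")
            d.add((gene, URIRef(iri("has measurement")), sc))
            d.add((sc, URIRef(iri("has value")),
                   Literal(str(round(rng.uniform(0.0, 5.0), 2)), datatype=XSD.decimal)))
        lr = typed(f"log2_ratio_{i + 1}", "log2 ratio")
        d.add((gene, URIRef(iri("has expression")), lr))
        d.add((lr, URIRef(iri("has value")),
               Literal(str(round(rng.uniform(-2.0, 3.0), 2)), datatype=XSD.decimal)))
        for p in rng.sample(pathways, rng.randint(1, 2)):
            d.add((gene, URIRef(iri("participates in")), p))
        if rng.random() < 0.7:
            d.add((gene, URIRef(iri("annotated with")), rng.choice(gfs)))

    for i in range(2):
        r = typed(f"researcher_{i + 1}", "researcher")
        d.add((r, URIRef(iri("has name")), Literal(f"researcher {chr(65 + i)}")))
        se = typed(f"sequence_extraction_{i + 1}", "sequence extraction")
        d.add((se, URIRef(iri("has agent")), r))
        dr = typed(f"drug_resistance_{i + 1}", "drug resistance")
        d.add((dr, RDFS.label, Literal("Neomycin resistance")))
        d.add((dr, URIRef(iri("has value")),
               Literal(str(round(rng.uniform(0.5, 2.0), 2)), datatype=XSD.decimal)))
        d.add((se, URIRef(iri("has output value")), dr))
    return d, gf_literals


# -- corpus ----------------------------------------------------------------

@dataclass
class GeneratedQuestion:
    """One corpus item with all gold layers."""

    question: str
    tokens: list
    labels: list  # per-token upper-level label or OUTSIDE
    entities: list  # RecognizedEntity (gold spans)
    elements: dict  # entity text -> element iri (gold matches)
    comparatives: list = field(default_factory=list)
    triples: TripleSequence | None = None
    target_var: str | None = None
    answers: list | None = None  # gold answer rows (tuples) or None


def _segments_to_item(segments, abbreviations=None):
    """segments: list of (text, upper_label_or_None, element_name_or_None).

    Returns (question text, tokens, labels, entities) where tokens equal
    the pipeline's preprocessed tokens.
    """
    from .preprocess import NUMBER_WORDS, default_abbreviations

    abbreviations = default_abbreviations() if abbreviations is None else abbreviations
    question = " ".join(s for s, _, _ in segments if s)
    tokens, labels, entities = [], [], []
    for text, label, element in segments:
        if not text:
            continue
        segtoks = []
        for tok in tokenize(text):
            if tok in abbreviations:
                segtoks.append(abbreviations[tok])
            elif tok.lower() in NUMBER_WORDS:
                segtoks.append(NUMBER_WORDS[tok.lower()])
            else:
                segtoks.append(tok)
        start = len(tokens)
        tokens.extend(segtoks)
        labels.extend([label or OUTSIDE] * len(segtoks))
        if label is not None:
            entities.append(RecognizedEntity(start, len(tokens),
                                             " ".join(segtoks), label))
    return question, tokens, labels, entities


def _gold_measure_answers(fixture: Fixture, link: str, measured: str, comps: list):
    """Distinct (gene, value...) rows satisfying the comparatives, by direct scan."""
    d = fixture.data
    link_p = URIRef(iri(link))
    value_p = URIRef(iri("has value"))
    cls = URIRef(iri(measured))
    rows = set()
    for gene, obj in d.subject_objects(link_p):
        if (obj, RDF.type, cls) not in d:
            continue
        values = list(d.objects(obj, value_p))
        if not comps:
            rows.add((str(gene),))
            continue
        for v in values:
            x = float(v)
            ok = all(_cmp(x, op, val) for _, op, val in comps)
            if ok:
                rows.add((str(gene), str(v)))
    return sorted(rows)


def _cmp(x, op, val):
    return {"<": x < val, ">": x > val, "<=": x <= val, ">=": x >= val,
            "=": x == val}[op]


def _measure_triples(link: str, measured: str, comps: list) -> TripleSequence:
    """Gold triple sequence for a gene -> measurement pattern."""
    classes = sorted([iri("gene"), iri(measured)])
    var_of = {c: f"?v{i}" for i, c in enumerate(classes)}
    triples = [(var_of[iri("gene")], iri(link), var_of[iri(measured)])]
    filters = []
    if comps:
        lit = "?lit0"
        triples.append((var_of[iri(measured)], iri("has value"), lit))
        filters = [(lit, op, val) for _, op, val in comps]
    return TripleSequence(triples, {v: c for c, v in var_of.items()}, filters)


def _researcher_triples() -> TripleSequence:
    classes = sorted([iri("sequence extraction"), iri("researcher"),
                      iri("drug resistance")])
    var_of = {c: f"?v{i}" for i, c in enumerate(classes)}
    se, r, dr = (var_of[iri("sequence extraction")], var_of[iri("researcher")],
                 var_of[iri("drug resistance")])
    return TripleSequence(
        [(se, iri("has agent"), r), (se, iri("has output value"), dr)],
        {v: c for c, v in var_of.items()},
    )


def _instance_triples(literal_text: str) -> TripleSequence:
    classes = sorted([iri("gene"), iri("gene function")])
    var_of = {c: f"?v{i}" for i, c in enumerate(classes)}
    gf_var = var_of[iri("gene function")]
    return TripleSequence(
        [(var_of[iri("gene")], iri("annotated with"), gf_var),
         (gf_var, str(RDFS.label), "?lit0")],
        {v: c for c, v in var_of.items()},
        literal_filters=[("?lit0", literal_text)],
    )


def generate_corpus(spec: FixtureSpec, fixture: Fixture):
    """Templated labeled corpus with gold matches, triples and answers.

    Returns (TrainingCorpus, list[GeneratedQuestion]).
    """
    rng = random.Random(f"{spec.seed}-corpus")
    questions = []

    measures = ["spectral count", "log2 ratio", "peptide count"]
    verbs = ["Find", "Show", "List", "Give"]

    def surface(cls_name: str) -> str:
        if rng.random() < spec.p_near_miss and cls_name in _ALIASES:
            return rng.choice(_ALIASES[cls_name])
        return cls_name

    def value_for(measure: str) -> float:
        v = round(rng.uniform(0.5, 4.0), 1) if measure != "log2 ratio" \
            else round(rng.uniform(-1.0, 2.0), 1)
        return 0.0 if v == 0 else v

    def comp_bucket() -> str:
        x = rng.random()
        acc = 0.0
        for name, frac in spec.template_mix.items():
            acc += frac
            if x < acc:
                return name
        return "no_comparative"

    link_of = {"spectral count": "has measurement", "log2 ratio": "has expression"}

    for _ in range(spec.corpus_size):
        kind = rng.random()
        if kind < spec.p_instance_entity:
            questions.append(_make_instance_question(spec, fixture, rng))
            continue
        if kind < spec.p_instance_entity + 0.12:
            questions.append(_make_researcher_question(fixture, rng))
            continue
        if kind < spec.p_instance_entity + 0.12 + 0.28:
            questions.append(_make_diversity_question(spec, fixture, rng))
            continue

        bucket = comp_bucket()
        measure = rng.choice(measures)
        if measure not in link_of:  # peptide count has no instance link; CRF-only
            v = value_for(measure)
            segs = [(rng.choice(verbs) + " all", None, None),
                    (surface("gene"), "material", "gene"),
                    ("with", None, None),
                    (surface(measure), "data collection", measure),
                    (f"greater than {v} .", None, None)]
            q, toks, labs, ents = _segments_to_item(segs)
            questions.append(GeneratedQuestion(
                q, toks, labs, ents,
                {e.text: iri(n) for e, n in zip(ents, ["gene", measure])},
                [ComparativeRelation(measure, ">", v)]))
            continue

        link = link_of[measure]
        msurf = surface(measure)
        gsurf = surface("gene")
        if bucket == "no_comparative":
            segs = [(rng.choice(verbs) + " all", None, None),
                    (gsurf, "material", "gene"), ("with", None, None),
                    (msurf, "data collection", measure), (".", None, None)]
            comps = []
        elif bucket == "one_comparative":
            v = value_for(measure)
            word = rng.choice(["greater than", "higher than", "above", "more than",
                               "less than", "below", "under", "at least", "at most"])
            segs = [(rng.choice(verbs) + " all", None, None),
                    (gsurf, "material", "gene"), ("with", None, None),
                    (msurf, "data collection", measure),
                    (f"{word} {v} .", None, None)]
            op = {"greater than": ">", "higher than": ">", "above": ">",
                  "more than": ">", "less than": "<", "below": "<",
                  "under": "<", "at least": ">=", "at most": "<="}[word]
            comps = [ComparativeRelation(measure, op, v)]
        else:
            v1 = value_for(measure)
            v2 = round(v1 + rng.choice([0.5, 1.0, 1.5]), 1)
            segs = [("Which", None, None), (gsurf, "material", "gene"),
                    ("have", None, None), (msurf, "data collection", measure),
                    (f"between {v1} and {v2} ?", None, None)]
            comps = [ComparativeRelation(measure, ">", v1),
                     ComparativeRelation(measure, "<", v2)]

        q, toks, labs, ents = _segments_to_item(segs)
        ts = _measure_triples(link, measure, [(None, c.operator, c.value) for c in comps])
        answers = _gold_measure_answers(fixture, link, measure,
                                        [(None, c.operator, c.value) for c in comps])
        gene_var = next(v for v, c in ts.var_classes.items() if c == iri("gene"))
        questions.append(GeneratedQuestion(
            q, toks, labs, ents,
            {e.text: iri(n) for e, n in zip(ents, ["gene", measure])},
            comps, ts, gene_var, answers))

    corpus = TrainingCorpus([(q.tokens, q.labels) for q in questions])
    return corpus, questions


def _make_instance_question(spec, fixture, rng):
    text = rng.choice(fixture.gf_literals)
    segs = [("Give the", None, None), ("genes", "material", "gene"),
            ("annotated as", None, None), (text, "parameter", None),
            (".", None, None)]
    q, toks, labs, ents = _segments_to_item(segs)
    ts = _instance_triples(text)
    d = fixture.data
    gf_insts = {s for s in d.subjects(RDF.type, URIRef(iri("gene function")))
                if str(d.value(s, RDFS.label)) == text}
    rows = sorted({(str(g), text) for gf in gf_insts
                   for g in d.subjects(URIRef(iri("annotated with")), gf)})
    gene_var = next(v for v, c in ts.var_classes.items() if c == iri("gene"))
    return GeneratedQuestion(q, toks, labs, ents,
                             {ents[0].text: iri("gene"),
                              ents[1].text: iri("gene function")},
                             [], ts, gene_var, rows)


def _make_researcher_question(fixture, rng):
    segs = [("Which", None, None), ("researchers", "agent", "researcher"),
            ("study", None, None), ("Neomycin resistance", "data collection",
                                    "drug resistance"),
            ("?", None, None)]
    q, toks, labs, ents = _segments_to_item(segs)
    ts = _researcher_triples()
    d = fixture.data
    rows = set()
    for se in d.subjects(RDF.type, URIRef(iri("sequence extraction"))):
        agents = list(d.objects(se, URIRef(iri("has agent"))))
        outs = [o for o in d.objects(se, URIRef(iri("has output value")))
                if (o, RDF.type, URIRef(iri("drug resistance"))) in d]
        if outs:
            rows.update((str(a),) for a in agents)
    r_var = next(v for v, c in ts.var_classes.items() if c == iri("researcher"))
    return GeneratedQuestion(q, toks, labs, ents,
                             {ents[0].text: iri("researcher"),
                              ents[1].text: iri("drug resistance")},
                             [], ts, r_var, sorted(rows))


def _make_diversity_question(spec, fixture, rng):
    """CRF/matching-only questions covering the remaining branches."""
    kind = rng.randrange(5)
    if kind == 0:
        instr = rng.choice(["mass spectrometer", "microarray chip"])
        proc = rng.choice(["protein identification", "microarray analysis"])
        segs = [("What", None, None), (instr, "instrument", instr),
                ("was used in", None, None), (proc, "process", proc),
                ("?", None, None)]
        names = [instr, proc]
    elif kind == 1:
        just = rng.choice(["experiment justification", "hypothesis statement"])
        proc = rng.choice(["cell cloning", "drug selection", "transfection"])
        segs = [("Show the", None, None), (just, "justification", just),
                ("for", None, None), (proc, "process", proc),
                (".", None, None)]
        names = [just, proc]
    elif kind == 2:
        pe = rng.choice(["pathway", "metabolic pathway"])
        segs = [("Find all", None, None), (surfaced(pe, spec, rng), "pathway element", pe),
                ("for", None, None), (surfaced("gene", spec, rng), "material", "gene"),
                (".", None, None)]
        names = [pe, "gene"]
    elif kind == 3:
        par = rng.choice(["gene function", "drug concentration"])
        segs = [("Give the", None, None), (par, "parameter", par),
                ("for all", None, None), (surfaced("gene", spec, rng), "material", "gene"),
                (".", None, None)]
        names = [par, "gene"]
    else:
        # abbreviation style: 5' expands to "five prime"
        segs = [("Find", None, None), ("5' forward region", "data collection",
                                       "five prime forward region"),
                ("for all", None, None), (surfaced("gene", spec, rng),
                                          "material", "gene"),
                (".", None, None)]
        names = ["five prime forward region", "gene"]
    q, toks, labs, ents = _segments_to_item(segs)
    elements = {e.text: iri(n) for e, n in zip(ents, names)}
    return GeneratedQuestion(q, toks, labs, ents, elements)


def surfaced(cls_name, spec, rng):
    if rng.random() < spec.p_near_miss and cls_name in _ALIASES:
        return rng.choice(_ALIASES[cls_name])
    return cls_name


# -- emission --------------------------------------------------------------

def emit(fixture: Fixture, corpus: TrainingCorpus, questions: list, outdir):
    """Write ontology.ttl, data.ttl, corpus.conll, gold_matches.tsv,
    gold_answers.json into ``outdir``."""
    from .recognition import corpus_to_conll

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# generated with seed {fixture.spec.seed}\n"
    (out / "ontology.ttl").write_text(header + fixture.ontology.serialize(format="turtle"))
    (out / "data.ttl").write_text(header + fixture.data.serialize(format="turtle"))
    (out / "corpus.conll").write_text(corpus_to_conll(corpus))
    lines = [f"# seed {fixture.spec.seed}"]
    for i, q in enumerate(questions):
        for text, el in q.elements.items():
            lines.append(f"{i}\t{text}\t{el or ''}")
    (out / "gold_matches.tsv").write_text("\n".join(lines) + "\n")
    answers = {
        str(i): {"question": q.question, "rows": q.answers}
        for i, q in enumerate(questions) if q.answers is not None
    }
    (out / "gold_answers.json").write_text(json.dumps(
        {"seed": fixture.spec.seed, "answers": answers}, indent=2))
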