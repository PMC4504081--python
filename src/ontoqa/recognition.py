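"""Entity recognition with a linear-chain CRF over BIO tags.

Each question token is featurized with the token string, the orthographic
indicator features below, a collapsed word-shape feature, contextual
token/shape features in a +/-2 window, and a dictionary feature that
fires the upper-level label of the best-matching ontology element for
noun/verb chunks whose similarity clears a threshold.  Upper-level
entity labels are encoded as B-/I- tags for training and merged back to
spans on output.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from statistics import mean, pstdev

from . import similarity as sim
from .crf import LinearChainCRF, TrainingError
from .ontology import OntologyModel
from .preprocess import ProcessedQuestion, pos_tag

OUTSIDE = "O"

#: orthographic indicator features and their regular expressions
ORTHOGRAPHIC = {
    "HASDASH": r".*-.*",
    "INITDASH": r"-.*",
    "ENDDASH": r".*-",
    "INITCAPS": r"[A-Z].*",
    "INITCAPSALPHA": r"[A-Z][a-z].*",
    "REALNUMBERS": r"[-0-9]+[.,]+[0-9.,]+",
    "NATURALNUMBER": r"[0-9]+",
    "ALLCAPS": r"[A-Z]+",
    "CAPSMIX": r"[A-Za-z]+",
    "DIGIT": r".*[0-9].*",
    "SINGLEDIGIT": r"[0-9]",
    "DOUBLEDIGIT": r"[0-9][0-9]",
    "GENEPATT": r".*[tbglmjfrnix0-9]+[.][0-9]+.*",
    "DNASEQUENCE": r"[ACTG]+",
    "HASROMAN": r".*\b[IVXDLCM]+\b.",
    "ROMAN": r"[IVXDLCM]+",
}
_ORTHO_COMPILED = {name: re.compile(rx) for name, rx in ORTHOGRAPHIC.items()}


class LabelSetError(ValueError):
    pass


@dataclass(frozen=True)
class RecognizedEntity:
    """A labeled token span (half-open over token indices)."""

    start: int
    end: int
    text: str
    label: str

    def __post_init__(self):
        assert 0 <= self.start < self.end


@dataclass
class TrainingCorpus:
    """Token sequences with aligned upper-level label sequences."""

    items: list = field(default_factory=list)  # (tokens, labels)
    label_set: set = field(default_factory=set)

    def __post_init__(self):
        for tokens, labels in self.items:
            assert len(tokens) == len(labels)
        if not self.label_set:
            self.label_set = {l for _, ls in self.items for l in ls if l != OUTSIDE}

    def __len__(self):
        return len(self.items)


def word_shape(token: str) -> str:
    shape = re.sub(r"[a-z]", "x", token)
    shape = re.sub(r"[A-Z]", "X", shape)
    shape = re.sub(r"[0-9]", "d", shape)
    return re.sub(r"(.)\1+", r"\1", shape)  # collapse runs


def orthographic_features(token: str) -> list:
    return [name for name, rx in _ORTHO_COMPILED.items() if rx.fullmatch(token)]


def _chunks(tokens: list, tags: list) -> list:
    """Maximal runs of noun/verb tokens, as (start, end) spans."""
    spans = []
    start = None
    for i, tag in enumerate(tags):
        if tag in ("NN", "VB"):
            if start is None:
                start = i
        elif start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(tags)))
    return spans


def dictionary_features(
    tokens: list,
    model: OntologyModel,
    upper_of: dict,
    sim_threshold: float = 0.6,
    measure: str = "isub",
) -> list:
    """Per-token dictionary features: for each noun/verb chunk, the
    upper-level ancestor of the best-matching ontology element, when the
    best similarity clears the threshold."""
    feats = [[] for _ in tokens]
    tags = pos_tag(tokens)
    names = [(el, model.name_of(el)) for el in sorted(model.elements())]
    for start, end in _chunks(tokens, tags):
        text = " ".join(tokens[start:end])
        best_el, best_score = None, 0.0
        for el, name in names:
            s = sim.similarity(text, name, measure)
            if s > best_score:
                best_el, best_score = el, s
        if best_el is not None and best_score >= sim_threshold:
            upper = upper_of.get(best_el)
            if upper is not None:
                for i in range(start, end):
                    feats[i].append(f"DICT={model.name_of(upper)}")
    return feats


def upper_ancestor_map(model: OntologyModel) -> dict:
    """Element -> nearest upper-level (C_O) ancestor, by breadth-first walk
    up the subclass hierarchy (a property maps through its domain classes)."""
    uppers = set(model.upper_labels)

    def nearest(cls: str):
        frontier = [cls]
        seen = set(frontier)
        while frontier:
            hits = sorted(c for c in frontier if c in uppers)
            if hits:
                return hits[0]
            nxt = []
            for c in frontier:
                for p in model.parents_of(c):
                    if p not in seen:
                        seen.add(p)
                        nxt.append(p)
            frontier = nxt
        return None

    out = {}
    for cls in model.classes:
        up = nearest(cls)
        if up is not None:
            out[cls] = up
    for iri, prop in model.properties.items():
        if iri in uppers:
            out[iri] = iri
            continue
        ups = sorted(filter(None, (nearest(d) for d in prop.domains)))
        if ups:
            out[iri] = ups[0]
    return out


def featurize(
    tokens: list,
    model: OntologyModel | None = None,
    sim_threshold: float = 0.6,
    upper_of: dict | None = None,
    window: int = 2,
) -> list:
    """Feature sets per token: string, orthographic, shape, context, dictionary."""
    feats = []
    shapes = [word_shape(t) for t in tokens]
    for i, tok in enumerate(tokens):
        f = [f"W={tok.lower()}", f"SHAPE={shapes[i]}"]
        f += orthographic_features(tok)
        for off in range(-window, window + 1):
            if off == 0:
                continue
            j = i + off
            if 0 <= j < len(tokens):
                f.append(f"W[{off}]={tokens[j].lower()}")
                f.append(f"SHAPE[{off}]={shapes[j]}")
            else:
                f.append(f"BOUND[{off}]")
        feats.append(f)
    if model is not None:
        if upper_of is None:
            upper_of = upper_ancestor_map(model)
        for f, extra in zip(feats, dictionary_features(tokens, model, upper_of, sim_threshold)):
            f.extend(extra)
    return feats


def to_bio(labels: list) -> list:
    bio = []
    prev = OUTSIDE
    for l in labels:
        if l == OUTSIDE:
            bio.append(OUTSIDE)
        elif l == prev:
            bio.append(f"I-{l}")
        else:
            bio.append(f"B-{l}")
        prev = l
    return bio


def spans_from_bio(tokens: list, bio: list) -> list:
    """Merge maximal runs of identical non-outside labels into entities."""
    entities = []
    start, label = None, None
    for i, tag in enumerate(bio + [OUTSIDE]):
        cur = tag[2:] if tag != OUTSIDE else None
        boundary = tag.startswith("B-") or cur != label
        if start is not None and boundary:
            entities.append(RecognizedEntity(start, i, " ".join(tokens[start:i]), label))
            start = None
        if cur is not None and (tag.startswith("B-") or start is None):
            start, label = i, cur
    return entities


def train(
    corpus: TrainingCorpus,
    seed: int = 0,
    model: OntologyModel | None = None,
    sim_threshold: float = 0.6,
    l2: float = 1.0,
) -> LinearChainCRF:
    """Train the CRF on a labeled corpus (BIO-encoded), L-BFGS optimized."""
    if len(corpus) == 0:
        raise TrainingError("empty corpus")
    upper_of = upper_ancestor_map(model) if model is not None else None
    X = [featurize(toks, model, sim_threshold, upper_of) for toks, _ in corpus.items]
    Y = [to_bio(labels) for _, labels in corpus.items]
    crf = LinearChainCRF(l2=l2)
    crf.fit(X, Y, seed=seed)
    crf.meta = {"sim_threshold": sim_threshold}
    return crf


def recognize(
    q: ProcessedQuestion,
    crf: LinearChainCRF,
    model: OntologyModel | None = None,
    sim_threshold: float = 0.6,
    upper_of: dict | None = None,
) -> list:
    """Decode entities from a processed question, in question order."""
    if not q.tokens:
        return []
    feats = featurize(q.tokens, model, sim_threshold, upper_of)
    bio = crf.predict(feats)
    # masked-out tokens cannot anchor an entity
    bio = [t if q.kept_mask[i] else OUTSIDE for i, t in enumerate(bio)]
    return spans_from_bio(q.tokens, bio)


def _entity_prf(gold_entities: list, predicted: list):
    gold = {(e.start, e.end, e.label) for e in gold_entities}
    pred = {(e.start, e.end, e.label) for e in predicted}
    correct = len(gold & pred)
    precision = correct / len(pred) if pred else 0.0
    recall = correct / len(gold) if gold else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1, not pred


def evaluate_kfold(
    corpus: TrainingCorpus,
    k: int = 5,
    seed: int = 7,
    model: OntologyModel | None = None,
    sim_threshold: float = 0.6,
) -> dict:
    """Seeded random k-fold cross-validation of entity recognition.

    Recall is the proportion of gold entities correctly identified and
    labeled; precision the proportion of predicted entities whose spans
    and labels are correct.  Folds with no predictions report precision 0
    with a flag.
    """
    if k < 2 or k > len(corpus):
        raise ValueError(f"k={k} incompatible with corpus of {len(corpus)} items")
    rng = random.Random(seed)
    order = list(range(len(corpus)))
    rng.shuffle(order)
    folds = [order[i::k] for i in range(k)]
    upper_of = upper_ancestor_map(model) if model is not None else None
    rows = []
    flagged = False
    for f in range(k):
        test_idx = set(folds[f])
        train_items = [corpus.items[i] for i in order if i not in test_idx]
        crf = train(TrainingCorpus(train_items), seed=seed, model=model, sim_threshold=sim_threshold)
        golds, preds = [], []
        for i in sorted(test_idx):
            tokens, labels = corpus.items[i]
            golds.extend(
                (i, e.start, e.end, e.label) for e in spans_from_bio(tokens, to_bio(labels))
            )
            feats = featurize(tokens, model, sim_threshold, upper_of)
            preds.extend(
                (i, e.start, e.end, e.label) for e in spans_from_bio(tokens, crf.predict(feats))
            )
        gold, pred = set(golds), set(preds)
        correct = len(gold & pred)
        if not pred:
            flagged = True
        p = correct / len(pred) if pred else 0.0
        r = correct / len(gold) if gold else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        rows.append({"precision": p, "recall": r, "f1": f1})
    out = {"folds": rows, "no_prediction_flag": flagged}
    for m in ("precision", "recall", "f1"):
        vals = [r[m] for r in rows]
        out[f"mean_{m}"] = mean(vals)
        out[f"std_{m}"] = pstdev(vals)
    return out


# -- CoNLL-style corpus IO ------------------------------------------------

def corpus_to_conll(corpus: TrainingCorpus) -> str:
    blocks = [
        "\n".join(f"{t}\t{l}" for t, l in zip(tokens, labels))
        for tokens, labels in corpus.items
    ]
    return "\n\n".join(blocks) + "\n"


def corpus_from_conll(text: str) -> TrainingCorpus:
    items = []
    for block in text.strip().split("\n\n"):
        tokens, labels = [], []
        for line in block.splitlines():
            if line.strip():
                tok, lab = line.rsplit("\t", 1)
                tokens.append(tok)
                labels.append(lab)
        if tokens:
            items.append((tokens, labels))
    return TrainingCorpus(items)
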