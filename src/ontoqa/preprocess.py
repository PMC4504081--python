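"""Linguistic pre-processing of natural-language questions.

Tokenization, stop-word and punctuation masking (tokens are masked, never
deleted, so offsets survive), abbreviation expansion, number-word
normalization, lightweight part-of-speech tagging, and extraction of
comparative relations ("standard deviation below 0.5" -> (standard
deviation, <, 0.5)).

Part-of-speech tags come from a small lexicon + suffix rule tagger that
covers the closed-class words and defaults open-class words to nouns;
this is sufficient for the noun-run chunking the comparative extractor
and the entity-recognition dictionary feature rely on.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

_NUMBER_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")
_PUNCT_RE = re.compile(r"^[^\w]+$")

NUMBER_WORDS = {
    "zero": "0", "one": "1", "two": "2", "three": "3", "four": "4",
    "five": "5", "six": "6", "seven": "7", "eight": "8", "nine": "9",
    "ten": "10", "eleven": "11", "twelve": "12", "thirteen": "13",
    "fourteen": "14", "fifteen": "15", "sixteen": "16", "seventeen": "17",
    "eighteen": "18", "nineteen": "19", "twenty": "20", "thirty": "30",
    "forty": "40", "fifty": "50", "sixty": "60", "seventy": "70",
    "eighty": "80", "ninety": "90", "hundred": "100", "thousand": "1000",
}

_DETERMINERS = {"a", "an", "the", "all", "any", "each", "this", "that", "these", "those"}
_PREPOSITIONS = {"of", "in", "on", "at", "by", "for", "with", "from", "to", "as", "into", "per"}
_CONJUNCTIONS = {"and", "or", "but", "nor"}
_WH_WORDS = {"which", "what", "who", "whom", "whose", "where", "when", "how"}
_VERBS = {
    "be", "am", "is", "are", "was", "were", "been", "being", "do", "does", "did",
    "have", "has", "had", "show", "give", "find", "list", "get", "display",
    "tell", "identify", "study", "studies", "exist", "exists", "measure",
    "report", "annotated", "related", "involved", "correspond", "participate",
    "retrieve", "return", "contain", "contains", "include", "includes",
}
_NEGATION_WORDS = {"not", "except", "without", "neither", "nor", "n't"}
_AGGREGATE_PHRASES = ("how many", "average", "total number", "sum of", "group by", "count of")


class InputError(ValueError):
    """Empty or unusable question text."""


@dataclass(frozen=True)
class ComparativeRelation:
    """A numeric constraint extracted from the question."""

    operand: str
    operator: str  # one of < > <= >= =
    value: float

    def __post_init__(self):
        if not self.operand:
            raise ValueError("comparative operand must be nonempty")
        if self.value != self.value or self.value in (float("inf"), float("-inf")):
            raise ValueError("comparative value must be finite")


@dataclass
class ProcessedQuestion:
    """A tokenized, masked and normalized question."""

    raw_text: str
    tokens: list = field(default_factory=list)
    pos_tags: list = field(default_factory=list)
    kept_mask: list = field(default_factory=list)
    expansions: list = field(default_factory=list)  # (abbreviation, expansion)
    comparatives: list = field(default_factory=list)
    flags: list = field(default_factory=list)  # unsupported-question markers

    def content_tokens(self) -> list:
        return [t for t, k in zip(self.tokens, self.kept_mask) if k]

    def __post_init__(self):
        assert len(self.tokens) == len(self.pos_tags) == len(self.kept_mask)


def _load_resource(name: str) -> str:
    return importlib.resources.files("ontoqa.resources").joinpath(name).read_text()


def default_stopwords() -> set:
    return {w.strip() for w in _load_resource("stopwords.txt").splitlines() if w.strip()}


def default_abbreviations() -> dict:
    out = {}
    for line in _load_resource("abbreviations.tsv").splitlines():
        if line.strip():
            abbrev, expansion = line.split("\t")
            out[abbrev] = expansion
    return out


def default_comparative_rules() -> dict:
    return yaml.safe_load(_load_resource("comparatives.yaml"))


def tokenize(text: str) -> list:
    """Split text into word, number and punctuation tokens.

    Dotted identifiers (gene ids like ``Tc00.1047053509463.30``) stay one
    token; sentence-final punctuation is split off.
    """
    raw = re.findall(r"[A-Za-z0-9][\w.'/-]*|\S", text)
    tokens = []
    for tok in raw:
        while len(tok) > 1 and tok[-1] in ".,;:?!":
            # keep internal dots of identifiers/decimals, strip trailing ones
            if tok[-1] == "." and re.search(r"\d\.\d", tok) and not tok.endswith(".."):
                if re.match(r"^[+-]?\d+\.\d+$", tok) or re.search(r"[A-Za-z]", tok):
                    break
            tokens.append(tok[:-1])
            tok = tok[-1]
            break
        else:
            tokens.append(tok)
            continue
        tokens.append(tok)
    # re-attach a leading sign to numeric literals ("below -0.7")
    merged = []
    i = 0
    while i < len(tokens):
        if (tokens[i] in "+-" and i + 1 < len(tokens)
                and _NUMBER_RE.match(tokens[i + 1])
                and not (merged and _NUMBER_RE.match(merged[-1]))):
            merged.append(tokens[i] + tokens[i + 1])
            i += 2
        else:
            merged.append(tokens[i])
            i += 1
    return merged


def pos_tag(tokens: list) -> list:
    """Tag tokens with a coarse part-of-speech from lexicon + suffix rules."""
    tags = []
    for tok in tokens:
        low = tok.lower()
        if _PUNCT_RE.match(tok):
            tags.append("PUNCT")
        elif _NUMBER_RE.match(tok) or low in NUMBER_WORDS:
            tags.append("CD")
        elif low in _DETERMINERS:
            tags.append("DT")
        elif low in _PREPOSITIONS:
            tags.append("IN")
        elif low in _CONJUNCTIONS:
            tags.append("CC")
        elif low in _WH_WORDS:
            tags.append("WP")
        elif low in _VERBS:
            tags.append("VB")
        elif low.endswith("ly"):
            tags.append("RB")
        else:
            tags.append("NN")
    return tags


def preprocess(
    question: str,
    abbreviations: dict | None = None,
    stop_words: set | None = None,
    comparative_rules: dict | None = None,
) -> ProcessedQuestion:
    """Tokenize, mask, expand and normalize a question.

    Raises :class:`InputError` on empty/whitespace input.  Stop words and
    punctuation are masked out (``kept_mask`` false) rather than deleted.
    Abbreviations from the maintained list are expanded in place and
    recorded; number words become digits.
    """
    if not question or not question.strip():
        raise InputError("question is empty")
    abbreviations = default_abbreviations() if abbreviations is None else abbreviations
    stop_words = default_stopwords() if stop_words is None else stop_words

    tokens = tokenize(question)
    expansions = []
    norm = []
    for tok in tokens:
        if tok in abbreviations:
            expansions.append((tok, abbreviations[tok]))
            norm.append(abbreviations[tok])
        elif tok.lower() in NUMBER_WORDS:
            norm.append(NUMBER_WORDS[tok.lower()])
        else:
            norm.append(tok)
    tokens = norm
    tags = pos_tag(tokens)
    mask = [
        not (tag == "PUNCT" or tok.lower() in stop_words)
        for tok, tag in zip(tokens, tags)
    ]
    q = ProcessedQuestion(question, tokens, tags, mask, expansions)
    q.flags = detect_unsupported_phrasing(q)
    q.comparatives = extract_comparatives(q, comparative_rules)
    return q


def detect_unsupported_phrasing(q: ProcessedQuestion) -> list:
    """Flag question types the pipeline refuses: negation and aggregates."""
    flags = []
    lows = [t.lower() for t in q.tokens]
    if any(t in _NEGATION_WORDS for t in lows):
        flags.append("negation")
    text = " ".join(lows)
    if any(p in text for p in _AGGREGATE_PHRASES):
        flags.append("aggregate")
    return flags


def _canonical_tokens(tokens: list, rules: dict) -> list:
    """Step (i): rewrite surface comparative phrases to canonical patterns."""
    lows = [t.lower() for t in tokens]
    rewrite = sorted(rules["rewrite"].items(), key=lambda kv: -len(kv[0].split()))
    out = []
    i = 0
    while i < len(lows):
        matched = False
        for phrase, target in rewrite:
            words = phrase.split()
            if lows[i : i + len(words)] == words:
                out.extend(target.split())
                i += len(words)
                matched = True
                break
        if not matched:
            out.append(lows[i])
            i += 1
    # between X and Y -> greater than X and less than Y (strict bounds)
    final = []
    i = 0
    while i < len(out):
        if (
            out[i] == "between"
            and i + 3 < len(out)
            and _NUMBER_RE.match(out[i + 1])
            and out[i + 2] == "and"
            and _NUMBER_RE.match(out[i + 3])
        ):
            lo, hi = sorted((float(out[i + 1]), float(out[i + 3])))
            final.extend(["greater", "than", repr(lo) if lo != int(lo) else str(int(lo)),
                          "and", "less", "than", repr(hi) if hi != int(hi) else str(int(hi))])
            i += 4
        else:
            final.append(out[i])
            i += 1
    return final


def extract_comparatives(q: ProcessedQuestion, rules: dict | None = None) -> list:
    """Extract comparative relations from a processed question.

    Two steps: surface phrases are rewritten to canonical patterns
    ("below" -> less-than, "between X and Y" -> greater-than X and
    less-than Y), then each canonical pattern with a numeric literal in
    scope becomes an (operand, operator, value) relation whose operand is
    the governing noun run immediately before the pattern.  A pattern
    with no numeric literal in scope is skipped with a warning; a value
    expressed as a multiple of another noun phrase ("1.5 of the log2
    ratio") is a cross-class comparison the pipeline refuses, so it is
    flagged instead of extracted.
    """
    rules = default_comparative_rules() if rules is None else rules
    toks = _canonical_tokens(q.tokens, rules)
    tags = pos_tag(toks)
    canonical = sorted(rules["canonical"].items(), key=lambda kv: -len(kv[0].split()))
    stop = default_stopwords()

    relations = []
    i = 0
    while i < len(toks):
        op = None
        width = 0
        for phrase, symbol in canonical:
            words = phrase.split()
            if toks[i : i + len(words)] == words:
                op, width = symbol, len(words)
                break
        if op is None:
            i += 1
            continue
        # numeric literal in scope: next few tokens
        value = None
        j = i + width
        for k in range(j, min(j + 3, len(toks))):
            if _NUMBER_RE.match(toks[k]):
                value = float(toks[k])
                j = k
                break
        if value is None:
            logger.warning("comparative %r at token %d has no numeric literal in scope", op, i)
            i += width
            continue
        # cross-class arithmetic: "<n> of the <noun phrase>"
        k = j + 1
        if k < len(toks) and toks[k] == "of":
            k2 = k + 1
            if k2 < len(toks) and toks[k2] in _DETERMINERS:
                k2 += 1
            if k2 < len(toks) and tags[k2] == "NN":
                if "cross_class_comparison" not in q.flags:
                    q.flags.append("cross_class_comparison")
                logger.warning("cross-class comparison refused: %s", " ".join(toks[i : k2 + 2]))
                i = k2 + 1
                continue
        # operand: noun run immediately preceding the pattern
        end = i
        start = end
        while start > 0 and tags[start - 1] == "NN" and toks[start - 1] not in stop:
            start -= 1
        operand = " ".join(toks[start:end])
        if not operand and relations:
            operand = relations[-1].operand  # shared operand (rewritten "between")
        if not operand:
            logger.warning("comparative %r has no governing noun phrase; skipped", op)
            i = j + 1
            continue
        relations.append(ComparativeRelation(operand, op, value))
        i = j + 1
    return relations
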