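"""String similarity measures for ontology element matching.

Five measures, each returning a symmetric score in [0, 1] with 1.0 for
identical normalized strings: ISUB (iterated longest-common-substring
commonality minus difference, with the Winkler prefix improvement),
Levenshtein (edit distance normalized by the longer string, computed with
edlib), Smith-Waterman (local alignment score normalized by the longer
string), cosine over character-frequency vectors, and Jaccard over
whitespace token sets.

Strings are normalized before scoring: lowercased, camelCase split,
underscores and hyphens mapped to spaces, whitespace collapsed.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter

import edlib
from Bio import Align

logger = logging.getLogger(__name__)

MEASURES = ("isub", "levenshtein", "smith_waterman", "cosine", "jaccard")

_CAMEL_RE = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")

_sw_aligner = Align.PairwiseAligner()
_sw_aligner.mode = "local"
_sw_aligner.match_score = 1.0
_sw_aligner.mismatch_score = -1.0 / 3.0
_sw_aligner.open_gap_score = -1.0 / 3.0
_sw_aligner.extend_gap_score = -1.0 / 3.0


def normalize(s: str) -> str:
    s = _CAMEL_RE.sub(" ", s)
    s = re.sub(r"[_\-]+", " ", s).lower()
    return re.sub(r"\s+", " ", s).strip()


def _longest_common_substring(a: str, b: str):
    """(length, start_a, start_b) of the longest common substring."""
    best = (0, 0, 0)
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best[0]:
                    best = (cur[j], i - cur[j], j - cur[j])
        prev = cur
    return best


def isub(a: str, b: str, clamp: bool = True) -> float:
    """ISUB similarity (Stoilos-style), clamped to [0, 1].

    Commonality: iteratively find and remove the longest common
    substring, summing the removed lengths, scaled by both string
    lengths.  Difference: the product of the unmatched proportions,
    damped by a Hamacher t-norm with parameter p = 0.6.  A Winkler-style
    bonus rewards a shared prefix.  The raw score comm - diff + winkler
    lies in [-1, 1]; the published score range for matching is [0, 1], so
    negative values are clamped.
    """
    la, lb = len(a), len(b)
    ra, rb = a, b
    common = 0
    prefix = 0
    for i, (ca, cb) in enumerate(zip(a, b)):
        if ca != cb:
            break
        prefix = i + 1
    while ra and rb:
        length, ia, ib = _longest_common_substring(ra, rb)
        if length < 2:  # single-character matches carry no signal
            break
        common += length
        ra = ra[:ia] + ra[ia + length:]
        rb = rb[:ib] + rb[ib + length:]
    comm = 2.0 * common / (la + lb)
    ua = (la - common) / la
    ub = (lb - common) / lb
    p = 0.6
    denom = p + (1 - p) * (ua + ub - ua * ub)
    diff = 0.0 if denom == 0 else (ua * ub) / denom
    winkler = min(4, prefix) * 0.1 * (1.0 - comm)
    score = comm - diff + winkler
    if clamp:
        score = min(1.0, max(0.0, score))
    return score


def levenshtein(a: str, b: str) -> float:
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def smith_waterman(a: str, b: str) -> float:
    return float(_sw_aligner.score(a, b)) / max(len(a), len(b))


def cosine(a: str, b: str) -> float:
    ca, cb = Counter(a), Counter(b)
    dot = sum(ca[ch] * cb[ch] for ch in ca)
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb) if na and nb else 0.0


def jaccard(a: str, b: str) -> float:
    sa, sb = set(a.split()), set(b.split())
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


_DISPATCH = {
    "isub": isub,
    "levenshtein": levenshtein,
    "smith_waterman": smith_waterman,
    "cosine": cosine,
    "jaccard": jaccard,
}


def similarity(a: str, b: str, measure: str = "isub") -> float:
    """Normalized similarity of two phrases under the named measure."""
    if measure not in _DISPATCH:
        raise ValueError(f"unknown similarity measure {measure!r}; choose from {MEASURES}")
    na, nb = normalize(a), normalize(b)
    if not na or not nb:
        logger.warning("empty string in similarity(%r, %r); score 0", a, b)
        return 0.0
    if na == nb:
        return 1.0
    # canonical operand order: ISUB's iterated substring removal can
    # otherwise break ties differently per direction
    na, nb = sorted((na, nb))
    return float(_DISPATCH[measure](na, nb))
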