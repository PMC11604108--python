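"""Normalized syntactic similarity metrics over unicode strings.

All metrics return a similarity in [0, 1], with 1 for identical strings.
Conventions for degenerate inputs: two empty strings are identical (1.0);
one empty string matches nothing (0.0).

Normalizations of the underlying distances:

* ``levenshtein``: 1 - d_lev(a, b) / max(|a|, |b|), unit-cost edits.
* ``indel``: 1 - d_indel(a, b) / (|a| + |b|), insertions/deletions only
  (d_indel = |a| + |b| - 2 * LCS(a, b)).
* ``jaro`` / ``jarowinkler``: the standard definitions; Winkler prefix
  scale 0.1 over at most 4 common leading characters.
* ``jaccard``: |A ∩ B| / |A ∪ B| over character 3-gram sets of the strings
  padded with one leading and one trailing space, so every non-empty string
  contributes at least one trigram.
"""

from __future__ import annotations

from typing import Callable, Dict, FrozenSet

SYNTACTIC_METRICS = ("levenshtein", "jaro", "jarowinkler", "jaccard", "indel")

JACCARD_NGRAM_SIZE = 3
WINKLER_PREFIX_SCALE = 0.1
WINKLER_MAX_PREFIX = 4


def levenshtein_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (insertions, deletions, substitutions)."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _lcs_length(a: str, b: str) -> int:
    if not a or not b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def indel_distance(a: str, b: str) -> int:
    """Edit distance when only insertions and deletions are allowed."""
    return len(a) + len(b) - 2 * _lcs_length(a, b)


def jaro_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    if window < 0:
        window = 0
    a_flags = [False] * la
    b_flags = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not b_flags[j] and b[j] == ca:
                a_flags[i] = b_flags[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    # transpositions: matched characters out of order, halved
    b_matched = [b[j] for j in range(lb) if b_flags[j]]
    transpositions = sum(
        ca != cb for ca, cb in zip((a[i] for i in range(la) if a_flags[i]), b_matched)
    )
    t = transpositions // 2
    m = matches
    return (m / la + m / lb + (m - t) / m) / 3.0


def jaro_winkler_similarity(a: str, b: str) -> float:
    jaro = jaro_similarity(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix == WINKLER_MAX_PREFIX:
            break
        prefix += 1
    return jaro + prefix * WINKLER_PREFIX_SCALE * (1.0 - jaro)


def char_ngrams(text: str, n: int = JACCARD_NGRAM_SIZE) -> FrozenSet[str]:
    """Set of character n-grams of ``text`` padded with one space each side."""
    if not text:
        return frozenset()
    padded = f" {text} "
    return frozenset(padded[i : i + n] for i in range(len(padded) - n + 1))


def jaccard_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    sa, sb = char_ngrams(a), char_ngrams(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def levenshtein_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / longest


def indel_similarity(a: str, b: str) -> float:
    if a == b:
        return 1.0
    total = len(a) + len(b)
    if total == 0:
        return 1.0
    return 1.0 - indel_distance(a, b) / total


_METRIC_FUNCS: Dict[str, Callable[[str, str], float]] = {
    "levenshtein": levenshtein_similarity,
    "jaro": jaro_similarity,
    "jarowinkler": jaro_winkler_similarity,
    "jaccard": jaccard_similarity,
    "indel": indel_similarity,
}


def syntactic_similarity(metric: str, a: str, b: str) -> float:
    """Normalized similarity in [0, 1] under the named metric.

    Both strings are expected to be normalized already (see
    :func:`ontoground.mappers.normalize`); no further preprocessing is done.
    """
    try:
        func = _METRIC_FUNCS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {', '.join(SYNTACTIC_METRICS)}"
        ) from None
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    return func(a, b)
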