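"""Independent brute-force oracles used to validate the implementation.

Everything here is written from the textbook definitions with no code shared
with the package: dense numpy TF-IDF + cosine over explicit n-gram counts,
full-matrix dynamic programming for edit distances, explicit set
construction for Jaccard, and a two-pass reference Jaro.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, List, Sequence, Tuple

import numpy as np


# --------------------------------------------------------------------------
# Dense TF-IDF + cosine (standard smooth-idf convention, l2 normalization)


def _ngram_counts(text: str, n: int) -> Counter:
    return Counter(text[i : i + n] for i in range(len(text) - n + 1))


def dense_tfidf_cosine(
    queries: Sequence[str], docs: Sequence[str], n: int
) -> np.ndarray:
    """Cosine similarity matrix (len(queries) x len(docs)).

    IDF is fitted on docs plus the non-empty queries (shared vocabulary),
    idf(t) = ln((1 + N) / (1 + df(t))) + 1, vectors are raw-count * idf,
    l2-normalized.  Inputs are already normalized and padded strings.
    """
    fit_docs = list(docs) + [q for q in queries if q]
    vocab = sorted({g for d in fit_docs for g in _ngram_counts(d, n)})
    vindex = {g: i for i, g in enumerate(vocab)}
    df = np.zeros(len(vocab))
    for d in fit_docs:
        for g in set(_ngram_counts(d, n)):
            df[vindex[g]] += 1
    idf = np.log((1 + len(fit_docs)) / (1 + df)) + 1.0

    def vec(s: str) -> np.ndarray:
        v = np.zeros(len(vocab))
        for g, c in _ngram_counts(s, n).items():
            if g in vindex:
                v[vindex[g]] = c
        v = v * idf
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v

    qm = np.array([vec(q) for q in queries]) if queries else np.zeros((0, len(vocab)))
    dm = np.array([vec(d) for d in docs])
    return qm @ dm.T


def ranked_oracle(
    sims_row: np.ndarray,
    corpus: Sequence,
    max_mappings: int,
    min_score: float,
) -> List[Tuple[str, float]]:
    """Collapse name scores to the best per term, rank, truncate, filter."""
    per_term: Dict[str, float] = {}
    for j, entry in enumerate(corpus):
        s = float(sims_row[j])
        if s > per_term.get(entry.term_iri, -1.0):
            per_term[entry.term_iri] = s
    ranked = sorted(per_term.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        (iri, s) for iri, s in ranked[:max_mappings] if s >= min_score and s > 0.0
    ]


# --------------------------------------------------------------------------
# Edit distances, full-matrix DP


def dp_levenshtein(a: str, b: str) -> int:
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[m][n]


def dp_indel(a: str, b: str) -> int:
    """Insert/delete-only edit distance via full DP (no substitutions)."""
    m, n = len(a), len(b)
    d = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        d[i][0] = i
    for j in range(n + 1):
        d[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            if a[i - 1] == b[j - 1]:
                d[i][j] = d[i - 1][j - 1]
            else:
                d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1)
    return d[m][n]


def set_jaccard(a: str, b: str, n: int = 3) -> float:
    """Jaccard over padded character n-gram sets, by explicit construction."""
    if a == b:
        return 1.0
    pa, pb = f" {a} ", f" {b} "
    sa = {pa[i : i + n] for i in range(len(pa) - n + 1)}
    sb = {pb[i : i + n] for i in range(len(pb) - n + 1)}
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)


def reference_jaro(a: str, b: str) -> float:
    """Two-pass reference Jaro: explicit match marking, then transposition
    count over the aligned match sequences."""
    if a == b:
        return 1.0
    if not a or not b:
        return 0.0
    window = max(0, max(len(a), len(b)) // 2 - 1)
    match_a: List[int] = []
    used_b = set()
    for i in range(len(a)):
        for j in range(max(0, i - window), min(len(b), i + window + 1)):
            if j not in used_b and a[i] == b[j]:
                match_a.append(i)
                used_b.add(j)
                break
    m = len(match_a)
    if m == 0:
        return 0.0
    sa = [a[i] for i in match_a]
    sb = [b[j] for j in sorted(used_b)]
    # out-of-order count is halved with integer division, the convention of
    # the canonical implementations (an odd count occurs when three or more
    # matched characters are cyclically permuted)
    t = sum(x != y for x, y in zip(sa, sb)) // 2
    return (m / len(a) + m / len(b) + (m - t) / m) / 3


def reference_jaro_winkler(a: str, b: str, p: float = 0.1, max_l: int = 4) -> float:
    j = reference_jaro(a, b)
    l = 0
    while l < min(max_l, len(a), len(b)) and a[l] == b[l]:
        l += 1
    return j + l * p * (1 - j)


# --------------------------------------------------------------------------
# Hierarchy closure by breadth-first search over an explicit edge list


def bfs_ancestors(parents: Dict[str, set], start: str) -> set:
    out = set()
    frontier = set(parents.get(start, set()))
    while frontier:
        out |= frontier
        frontier = {g for f in frontier for g in parents.get(f, set())} - out
    return out
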