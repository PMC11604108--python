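"""Scored candidate mapping of source strings to ontology terms.

Two offline mapper families are provided:

* :func:`tfidf_map` — strings are embedded as TF-IDF vectors over character
  n-grams (default size 3, computed on the normalized string padded with one
  leading and trailing space) and compared by cosine similarity.  The whole
  batch reduces to one sparse matrix product, which is what makes this
  mapper fast on large ontologies.
* :func:`syntactic_map` — classic pairwise edit-distance style metrics
  (Levenshtein, Jaro, Jaro-Winkler, Jaccard, Indel), normalized to [0, 1].

Both share a ranking contract: per source term, candidate ontology terms are
scored by their best matching name (label or synonym), ranked by descending
score with ties broken by IRI, truncated to ``max_mappings`` and filtered at
``min_score``.

Normalization is deliberately minimal — lowercasing, unicode NFC, whitespace
collapse — and removes no tokens, so inputs like "non-hodgkin's lymphoma"
keep their negation prefix instead of losing it to a stop-word list.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import TfidfVectorizer

from .metrics import SYNTACTIC_METRICS, syntactic_similarity
from .model import OntologyIndex

MAPPERS = ("tfidf",) + SYNTACTIC_METRICS + ("bioportal", "zooma")

#: preference order when the same name is asserted under several properties
_KIND_ORDER = {"label": 0, "exact_synonym": 1, "broad_synonym": 2}


def normalize(text: str) -> str:
    """Normalize a string for matching.

    Lowercase, unicode NFC, collapse runs of whitespace to single spaces,
    strip surrounding space.  No token is ever removed.
    """
    text = unicodedata.normalize("NFC", text).lower()
    return " ".join(text.split())


@dataclass(frozen=True)
class NameEntry:
    """One matchable name (label or synonym) of an ontology term."""

    term_iri: str
    name: str
    name_kind: str  # label | exact_synonym | broad_synonym


@dataclass(frozen=True)
class MapperConfig:
    """Mapper selection and scoring parameters.

    ``tfidf_fit`` controls the IDF fitting corpus: ``"union"`` (default)
    fits on ontology names plus the query batch so both sides share one
    vocabulary; ``"ontology"`` fits on ontology names alone, making scores
    independent of the query batch.
    """

    mapper: str = "tfidf"
    ngram_size: int = 3
    max_mappings: int = 3
    min_score: float = 0.3
    tfidf_fit: str = "union"

    def __post_init__(self) -> None:
        if self.mapper not in MAPPERS:
            raise ValueError(
                f"unknown mapper {self.mapper!r}; expected one of {', '.join(MAPPERS)}"
            )
        if self.ngram_size < 1:
            raise ValueError("ngram_size must be >= 1")
        if self.max_mappings < 1:
            raise ValueError("max_mappings must be >= 1")
        if not 0.0 <= self.min_score <= 1.0:
            raise ValueError("min_score must lie in [0, 1]")
        if self.tfidf_fit not in ("union", "ontology"):
            raise ValueError("tfidf_fit must be 'union' or 'ontology'")


@dataclass(frozen=True)
class RawMatch:
    """One scored (source term -> ontology term) candidate."""

    source_index: int
    term_iri: str
    matched_name: str
    name_kind: str
    score: float


class CorpusError(Exception):
    """The ontology yields no matchable names."""


def build_name_corpus(index: OntologyIndex, include_broad: bool = False) -> List[NameEntry]:
    """One entry per normalized label/synonym of every matchable term.

    Names are deduplicated per term after normalization, keeping the most
    specific kind (label over exact synonym over broad synonym); the result
    is sorted by (term IRI, name) so corpus order is deterministic.
    """
    entries: List[NameEntry] = []
    for term in index.matchable_terms():
        seen: Dict[str, str] = {}
        pools = [("label", term.labels), ("exact_synonym", term.exact_synonyms)]
        if include_broad:
            pools.append(("broad_synonym", term.broad_synonyms))
        for kind, names in pools:
            for raw in names:
                name = normalize(raw)
                if name and name not in seen:
                    seen[name] = kind
        entries.extend(
            NameEntry(term_iri=term.iri, name=name, name_kind=kind)
            for name, kind in seen.items()
        )
    if not entries:
        raise CorpusError(f"no matchable names in ontology {index.source}")
    entries.sort(key=lambda e: (e.term_iri, e.name))
    return entries


def _pad(text: str) -> str:
    return f" {text} " if text else ""


def _rank_matches(
    per_term: Dict[str, Tuple[float, str, str]],
    source_index: int,
    config: MapperConfig,
) -> List[RawMatch]:
    """Order candidate terms, truncate to max_mappings, filter at min_score."""
    ranked = sorted(per_term.items(), key=lambda kv: (-kv[1][0], kv[0]))
    out = []
    for iri, (score, name, kind) in ranked[: config.max_mappings]:
        if score >= config.min_score and score > 0.0:
            out.append(
                RawMatch(
                    source_index=source_index,
                    term_iri=iri,
                    matched_name=name,
                    name_kind=kind,
                    score=score,
                )
            )
    return out


def _collapse_to_terms(
    scores_names: Sequence[Tuple[float, NameEntry]],
) -> Dict[str, Tuple[float, str, str]]:
    """Best name per term; ties prefer labels, then lexicographic name."""
    per_term: Dict[str, Tuple[float, str, str]] = {}
    best_key: Dict[str, Tuple[float, int, str]] = {}
    for score, entry in scores_names:
        key = (-score, _KIND_ORDER[entry.name_kind], entry.name)
        if entry.term_iri not in best_key or key < best_key[entry.term_iri]:
            best_key[entry.term_iri] = key
            per_term[entry.term_iri] = (score, entry.name, entry.name_kind)
    return per_term


def tfidf_map(
    sources: Sequence[str],
    corpus: Sequence[NameEntry],
    config: Optional[MapperConfig] = None,
) -> List[RawMatch]:
    """Map source strings to ontology terms by TF-IDF n-gram cosine similarity.

    ``sources`` are raw strings; they are normalized here.  A source whose
    normalized, padded text yields no n-gram produces no matches (it will be
    reported as unmapped downstream, not as an error).
    """
    config = config or MapperConfig(mapper="tfidf")
    if not corpus:
        raise CorpusError("empty name corpus")

    queries = [_pad(normalize(s)) for s in sources]
    docs = [_pad(e.name) for e in corpus]

    vectorizer = TfidfVectorizer(
        analyzer="char",
        ngram_range=(config.ngram_size, config.ngram_size),
        lowercase=False,
        norm="l2",
    )
    fit_docs = docs if config.tfidf_fit == "ontology" else docs + [q for q in queries if q]
    vectorizer.fit(fit_docs)
    doc_matrix = vectorizer.transform(docs)
    query_matrix = vectorizer.transform(queries)

    # cosine similarity of l2-normalized vectors is a plain sparse product
    sims = query_matrix @ doc_matrix.T
    sims = sims.tocsr()

    results: List[RawMatch] = []
    for qi in range(len(sources)):
        row = sims.getrow(qi)
        if row.nnz == 0:
            continue
        pairs = [
            (min(float(v), 1.0), corpus[j]) for j, v in zip(row.indices, row.data) if v > 0.0
        ]
        per_term = _collapse_to_terms(pairs)
        results.extend(_rank_matches(per_term, qi, config))
    return results


def syntactic_map(
    sources: Sequence[str],
    corpus: Sequence[NameEntry],
    config: MapperConfig,
) -> List[RawMatch]:
    """Map source strings by pairwise comparison under a syntactic metric.

    The score of a (source, term) pair is the maximum similarity over all of
    the term's names; ranking, truncation and filtering follow the same
    contract as :func:`tfidf_map`.
    """
    if config.mapper not in SYNTACTIC_METRICS:
        raise ValueError(f"not a syntactic metric: {config.mapper!r}")
    if not corpus:
        raise CorpusError("empty name corpus")

    results: List[RawMatch] = []
    for qi, source in enumerate(sources):
        q = normalize(source)
        if not q:
            continue
        pairs = [(syntactic_similarity(config.mapper, q, e.name), e) for e in corpus]
        per_term = _collapse_to_terms(pairs)
        results.extend(_rank_matches(per_term, qi, config))
    return results
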