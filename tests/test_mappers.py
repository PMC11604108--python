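"""TF-IDF and syntactic mappers against dense brute-force oracles."""

import pytest

from ontoground import LoadConfig, load_ontology
from ontoground.fixtures import FixtureSpec, generate_toy_ontology
from ontoground.mappers import (
    CorpusError,
    MapperConfig,
    NameEntry,
    build_name_corpus,
    normalize,
    syntactic_map,
    tfidf_map,
)
from ontoground.metrics import SYNTACTIC_METRICS, syntactic_similarity

from .oracles import dense_tfidf_cosine, ranked_oracle


# --------------------------------------------------------------------------
# normalize


@pytest.mark.parametrize(
    "raw,expected",
    [
        ("Heart  Failure ", "heart failure"),
        ("non-Hodgkin's lymphoma", "non-hodgkin's lymphoma"),
        ("", ""),
        ("  MIXED\tCase\nText  ", "mixed case text"),
    ],
)
def test_normalize(raw, expected):
    """Casefold + whitespace collapse, and crucially no token removal:
    the 'non' negation prefix survives."""
    assert normalize(raw) == expected


# --------------------------------------------------------------------------
# corpus


def test_corpus_entries_match_ground_truth(toy):
    index, truth, _ = toy
    corpus = build_name_corpus(index, include_broad=True)
    by_iri = {}
    for e in corpus:
        by_iri.setdefault(e.term_iri, set()).add(e.name)
    for iri, t in truth.terms.items():
        if t.deprecated:
            assert iri not in by_iri
            continue
        expected = {normalize(n) for n in t.labels + t.exact_synonyms + t.broad_synonyms}
        assert by_iri[iri] == expected


def test_corpus_excludes_broad_when_not_requested(toy):
    index, truth, _ = toy
    corpus = build_name_corpus(index, include_broad=False)
    names = {(e.term_iri, e.name) for e in corpus}
    for iri, t in truth.terms.items():
        for b in t.broad_synonyms:
            if normalize(b) not in {normalize(x) for x in t.labels + t.exact_synonyms}:
                assert (iri, normalize(b)) not in names


def test_corpus_deduplicates_synonym_equal_to_label(mirror):
    index, _, _ = mirror
    term = index.terms["http://purl.obolibrary.org/obo/MONDO_0004975"]
    term.exact_synonyms.append(term.labels[0])  # duplicate after normalization
    try:
        corpus = build_name_corpus(index)
        entries = [e for e in corpus if e.term_iri == term.iri]
        assert len({e.name for e in entries}) == len(entries)
        labels = [e for e in entries if e.name == normalize(term.labels[0])]
        assert len(labels) == 1 and labels[0].name_kind == "label"
    finally:
        term.exact_synonyms.pop()


def test_corpus_is_deterministic_and_sorted(toy):
    index, _, _ = toy
    c1 = build_name_corpus(index)
    c2 = build_name_corpus(index)
    assert c1 == c2
    assert c1 == sorted(c1, key=lambda e: (e.term_iri, e.name))


# --------------------------------------------------------------------------
# tfidf


def _query_set(truth, k=50, seed=11):
    import random

    rng = random.Random(seed)
    queries = [q.query for q in truth.queries]
    rng.shuffle(queries)
    return queries[:k]


def test_tfidf_matches_dense_oracle_on_fixture(toy):
    """Ranked IRIs identical and scores within 1e-9 of a dense numpy
    TF-IDF + cosine computation over all (query, name) pairs."""
    index, truth, _ = toy
    corpus = build_name_corpus(index)
    queries = _query_set(truth)
    config = MapperConfig(mapper="tfidf", max_mappings=5, min_score=0.1)
    got = tfidf_map(queries, corpus, config)

    sims = dense_tfidf_cosine(
        [f" {normalize(q)} " for q in queries],
        [f" {e.name} " for e in corpus],
        3,
    )
    for qi in range(len(queries)):
        expected = ranked_oracle(sims[qi], corpus, config.max_mappings, config.min_score)
        mine = [(m.term_iri, m.score) for m in got if m.source_index == qi]
        assert [iri for iri, _ in mine] == [iri for iri, _ in expected], queries[qi]
        for (_, s1), (_, s2) in zip(mine, expected):
            assert s1 == pytest.approx(s2, abs=1e-9)


def test_tfidf_refind_all_labels(toy):
    """Each matchable term's own label comes back at rank 1 with score 1."""
    index, truth, _ = toy
    corpus = build_name_corpus(index)
    queries = [q.query for q in truth.queries]
    got = tfidf_map(queries, corpus, MapperConfig())
    best = {}
    for m in got:
        best.setdefault(m.source_index, m)
    for qi, q in enumerate(truth.queries):
        assert best[qi].term_iri == q.true_iri
        assert best[qi].score == pytest.approx(1.0, abs=1e-9)


def test_tfidf_synonym_match(mirror):
    index, _, _ = mirror
    corpus = build_name_corpus(index)
    got = tfidf_map(["heart attack"], corpus, MapperConfig())
    assert got[0].term_iri == "http://purl.obolibrary.org/obo/MONDO_0005068"
    assert got[0].score == pytest.approx(1.0, abs=1e-9)
    assert got[0].name_kind == "exact_synonym"


def test_tfidf_short_query_is_unmapped_not_error():
    corpus = [NameEntry("http://x/a", "alpha condition", "label")]
    got = tfidf_map([""], corpus, MapperConfig())
    assert got == []


def test_tfidf_truncation_is_prefix_monotone(toy):
    index, truth, _ = toy
    corpus = build_name_corpus(index)
    queries = _query_set(truth, k=20)
    for k in (1, 2, 3):
        small = tfidf_map(queries, corpus, MapperConfig(max_mappings=k, min_score=0.0))
        big = tfidf_map(queries, corpus, MapperConfig(max_mappings=k + 1, min_score=0.0))
        for qi in range(len(queries)):
            s = [(m.term_iri, m.score) for m in small if m.source_index == qi]
            b = [(m.term_iri, m.score) for m in big if m.source_index == qi]
            assert b[: len(s)] == s


def test_tfidf_min_score_filters(toy):
    index, truth, _ = toy
    corpus = build_name_corpus(index)
    queries = _query_set(truth, k=20)
    got = tfidf_map(queries, corpus, MapperConfig(min_score=0.6, max_mappings=10))
    assert all(m.score >= 0.6 for m in got)


def test_tfidf_deterministic(toy):
    index, truth, _ = toy
    corpus = build_name_corpus(index)
    queries = _query_set(truth, k=15)
    assert tfidf_map(queries, corpus, MapperConfig()) == tfidf_map(
        queries, corpus, MapperConfig()
    )


def test_tfidf_tie_break_by_iri():
    corpus = [
        NameEntry("http://x/b", "zeta syndrome", "label"),
        NameEntry("http://x/a", "zeta syndrome", "label"),
    ]
    got = tfidf_map(["zeta syndrome"], corpus, MapperConfig(max_mappings=2))
    assert [m.term_iri for m in got] == ["http://x/a", "http://x/b"]
    assert got[0].score == got[1].score


def test_empty_corpus_is_fatal():
    with pytest.raises(CorpusError):
        tfidf_map(["x"], [], MapperConfig())


# --------------------------------------------------------------------------
# syntactic_map


@pytest.mark.parametrize("metric", SYNTACTIC_METRICS)
def test_syntactic_map_matches_allpairs_oracle(toy, metric):
    """Identical ranked result set to a brute-force all-pairs computation."""
    index, truth, _ = toy
    corpus = build_name_corpus(index)[:80]
    queries = _query_set(truth, k=12, seed=4)
    config = MapperConfig(mapper=metric, max_mappings=4, min_score=0.2)
    got = syntactic_map(queries, corpus, config)
    for qi, q in enumerate(queries):
        nq = normalize(q)
        per_term = {}
        for e in corpus:
            s = syntactic_similarity(metric, nq, e.name)
            per_term[e.term_iri] = max(per_term.get(e.term_iri, 0.0), s)
        ranked = sorted(per_term.items(), key=lambda kv: (-kv[1], kv[0]))
        expected = [
            (iri, s) for iri, s in ranked[:4] if s >= 0.2 and s > 0.0
        ]
        mine = [(m.term_iri, m.score) for m in got if m.source_index == qi]
        assert mine == expected


@pytest.mark.parametrize("metric", SYNTACTIC_METRICS)
def test_syntactic_refind(toy, metric):
    index, truth, _ = toy
    corpus = build_name_corpus(index)
    queries = [q.query for q in truth.queries[:25]]
    got = syntactic_map(queries, corpus, MapperConfig(mapper=metric))
    best = {}
    for m in got:
        best.setdefault(m.source_index, m)
    for qi, q in enumerate(truth.queries[:25]):
        assert best[qi].term_iri == q.true_iri, (metric, q.query)
        assert best[qi].score == 1.0


def test_syntactic_single_term_corpus_reduces_to_similarity():
    corpus = [NameEntry("http://x/a", "kitten", "label")]
    got = syntactic_map(["sitting"], corpus, MapperConfig(mapper="levenshtein", min_score=0.0))
    assert len(got) == 1
    assert got[0].score == pytest.approx(1 - 3 / 7)


def test_mapper_config_validation():
    with pytest.raises(ValueError):
        MapperConfig(mapper="embedding")
    with pytest.raises(ValueError):
        MapperConfig(max_mappings=0)
    with pytest.raises(ValueError):
        MapperConfig(min_score=1.5)
    with pytest.raises(ValueError):
        MapperConfig(ngram_size=0)
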