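"""Ontology loading, extraction completeness, ancestor closure, caching."""

import pytest

from ontoground import LoadConfig, OntologyError, TermKindFilter, load_ontology
from ontoground.fixtures import FixtureSpec, generate_toy_ontology
from ontoground.model import derive_curie, fallback_name
from ontoground.ontology import load_cache, save_cache

from .oracles import bfs_ancestors


def test_extraction_completeness_against_ground_truth(toy):
    """Every label, synonym, definition and parent written by the generator
    is recovered exactly by the loader."""
    index, truth, _ = toy
    assert len(index) == len(truth.terms)
    for iri, t in truth.terms.items():
        term = index.terms[iri]
        assert term.labels == t.labels
        assert sorted(term.exact_synonyms) == t.exact_synonyms
        assert sorted(term.broad_synonyms) == t.broad_synonyms
        assert sorted(term.definitions) == t.definitions
        assert sorted(term.parents) == t.parents
        assert term.deprecated == t.deprecated
        assert term.curie == f"TOY:{iri[-7:]}"


def test_children_are_inverse_of_parents(toy):
    index, _, _ = toy
    for term in index.terms.values():
        for p in term.parents:
            assert term.iri in index.terms[p].children


def test_ancestors_equal_bruteforce_bfs_on_all_terms(toy):
    index, truth, _ = toy
    parent_map = {iri: set(t.parents) for iri, t in truth.terms.items()}
    for iri in index.terms:
        assert index.ancestors(iri) == bfs_ancestors(parent_map, iri)


def test_ancestors_monotone_and_chain(toy):
    """If p is a direct parent of x then ancestors(p) subset ancestors(x);
    the root has no ancestors."""
    index, _, _ = toy
    for term in index.terms.values():
        anc = index.ancestors(term.iri)
        for p in term.parents:
            assert index.ancestors(p) <= anc
    root = next(t for t in index.terms.values() if not t.parents)
    assert index.ancestors(root.iri) == frozenset()


def test_ancestors_unknown_iri_raises(toy):
    index, _, _ = toy
    with pytest.raises(OntologyError, match="unknown IRI"):
        index.ancestors("http://example.org/nope")


def test_ancestors_diamond(tmp_path):
    """A<B, A<C, B<D, C<D: ancestors(A) = {B, C, D}."""
    from ontoground.fixtures import TermTruth, _class_xml, _XML_HEAD

    iris = {k: f"http://purl.obolibrary.org/obo/TOY_000000{i}" for i, k in enumerate("ABCD")}
    parents = {"A": ["B", "C"], "B": ["D"], "C": ["D"], "D": []}
    doc = [_XML_HEAD]
    for k, iri in iris.items():
        doc.append(
            _class_xml(
                TermTruth(
                    iri=iri,
                    labels=[f"term {k}"],
                    exact_synonyms=[],
                    broad_synonyms=[],
                    definitions=[],
                    parents=[iris[p] for p in parents[k]],
                    deprecated=False,
                )
            )
        )
    doc.append("</rdf:RDF>\n")
    path = tmp_path / "diamond.owl"
    path.write_text("\n".join(doc))
    index = load_ontology(str(path))
    assert index.ancestors(iris["A"]) == {iris["B"], iris["C"], iris["D"]}
    assert index.ancestors(iris["D"]) == frozenset()


def test_cycle_terminates_and_includes_self(tmp_path):
    from ontoground.fixtures import TermTruth, _class_xml, _XML_HEAD

    a = "http://purl.obolibrary.org/obo/TOY_0000001"
    b = "http://purl.obolibrary.org/obo/TOY_0000002"
    doc = [_XML_HEAD]
    for iri, parent in ((a, b), (b, a)):
        doc.append(
            _class_xml(
                TermTruth(iri, [f"t{iri[-1]}"], [], [], [], [parent], False)
            )
        )
    doc.append("</rdf:RDF>\n")
    path = tmp_path / "cycle.owl"
    path.write_text("\n".join(doc))
    index = load_ontology(str(path))
    assert index.ancestors(a) == {a, b}


def test_deprecated_terms_loaded_flagged_but_unmatchable(toy):
    index, truth, _ = toy
    deprecated = [iri for iri, t in truth.terms.items() if t.deprecated]
    assert deprecated, "fixture should contain deprecated terms"
    matchable = {t.iri for t in index.matchable_terms()}
    for iri in deprecated:
        assert iri in index.terms
        assert index.terms[iri].deprecated
        assert iri not in matchable


def test_include_deprecated_config(toy):
    _, _, path = toy
    index = load_ontology(str(path), LoadConfig(include_deprecated=True))
    assert len(index.matchable_terms()) == len(index.terms)


def test_property_filter_on_class_only_ontology_is_fatal(toy):
    _, _, path = toy
    with pytest.raises(OntologyError, match="no terms extracted"):
        load_ontology(str(path), LoadConfig(term_kind_filter=TermKindFilter.PROPERTIES))


def test_base_iri_restriction(mirror):
    _, _, path = mirror
    efo_only = load_ontology(str(path), LoadConfig(base_iris=("http://www.ebi.ac.uk/efo/",)))
    assert all(t.iri.startswith("http://www.ebi.ac.uk/efo/") for t in efo_only.terms.values())
    assert len(efo_only) < len(load_ontology(str(path)))


def test_missing_and_unparseable_sources_are_fatal(tmp_path):
    with pytest.raises(OntologyError, match="not found"):
        load_ontology(str(tmp_path / "nope.owl"))
    bad = tmp_path / "bad.owl"
    bad.write_text("this is not an ontology {{{")
    with pytest.raises(OntologyError, match="could not parse"):
        load_ontology(str(bad))


def test_turtle_serialization_loads(tmp_path):
    ttl = """@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
<http://purl.obolibrary.org/obo/TOY_0000001> a owl:Class ;
    rdfs:label "solo condition" .
"""
    path = tmp_path / "solo.ttl"
    path.write_text(ttl)
    index = load_ontology(str(path))
    assert index.terms["http://purl.obolibrary.org/obo/TOY_0000001"].labels == ["solo condition"]


def test_exact_synonym_and_label_coexist(mirror):
    """The myocardial-infarction term carries both its label and the
    'heart attack' exact synonym, in the respective fields."""
    index, _, _ = mirror
    term = index.terms["http://purl.obolibrary.org/obo/MONDO_0005068"]
    assert term.labels == ["myocardial infarction"]
    assert term.exact_synonyms == ["heart attack"]


def test_curie_derivation_patterns():
    assert derive_curie("http://purl.obolibrary.org/obo/MONDO_0004975") == "MONDO:0004975"
    assert derive_curie("http://www.ebi.ac.uk/efo/EFO_0000249") == "EFO:0000249"
    assert derive_curie("http://example.org/random#X") == ""


def test_fallback_name_splits_fragment():
    assert fallback_name("http://example.org/onto#HeartFailure_acute") == "Heart Failure acute"


def test_cache_round_trip_is_identity(toy, tmp_path):
    index, _, _ = toy
    save_cache(index, tmp_path / "cache")
    loaded = load_cache(tmp_path / "cache")
    assert set(loaded.terms) == set(index.terms)
    for iri, term in index.terms.items():
        other = loaded.terms[iri]
        for attr in (
            "curie", "labels", "exact_synonyms", "broad_synonyms",
            "definitions", "parents", "children", "instances",
            "deprecated", "term_kind",
        ):
            assert getattr(other, attr) == getattr(term, attr), (iri, attr)
        assert loaded.ancestors(iri) == index.ancestors(iri)
    assert loaded.load_config == index.load_config
    assert loaded.source == index.source


def test_cache_missing_and_version_mismatch(tmp_path):
    with pytest.raises(OntologyError, match="missing cache"):
        load_cache(tmp_path)
    spec = FixtureSpec(n_terms=5, seed=1)
    doc, _ = generate_toy_ontology(spec)
    owl = tmp_path / "t.owl"
    owl.write_text(doc)
    index = load_ontology(str(owl))
    save_cache(index, tmp_path / "c")
    meta = tmp_path / "c" / "metadata.json"
    meta.write_text(meta.read_text().replace('"cache_format_major": 0', '"cache_format_major": 99'))
    with pytest.raises(OntologyError, match="re-cache"):
        load_cache(tmp_path / "c")


def test_cache_preserves_broad_synonyms(toy, tmp_path):
    index, truth, _ = toy
    save_cache(index, tmp_path / "bc")
    loaded = load_cache(tmp_path / "bc")
    has_broad = [iri for iri, t in truth.terms.items() if t.broad_synonyms]
    assert has_broad
    for iri in has_broad:
        assert sorted(loaded.terms[iri].broad_synonyms) == truth.terms[iri].broad_synonyms
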