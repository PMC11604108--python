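"""Load OWL ontologies and extract the term details used for matching.

The loader reads RDF/XML or Turtle from a local path or an http(s) URL and
collects, per term: labels (``rdfs:label``, ``skos:prefLabel``), exact
synonyms (``oboInOwl:hasExactSynonym``, the NCI Thesaurus ``P90`` property,
EFO's ``alternative_term``), optionally broad synonyms
(``oboInOwl:hasBroadSynonym``), definitions (``skos:definition``,
``IAO:0000115``), the asserted subclass/subproperty hierarchy, instances,
and deprecation flags.  Reasoning is off by default; a caller may supply a
reasoner hook that augments the parent edges before the closure is built.

A loaded index can be cached to a directory (JSON term table plus metadata)
and reloaded without reparsing the OWL document.
"""

from __future__ import annotations

import json
import logging
import tempfile
import urllib.error
import urllib.request
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Set

import rdflib
from rdflib import RDF, RDFS, OWL, URIRef

from .model import (
    LoadConfig,
    OntologyError,
    OntologyIndex,
    OntologyTerm,
    TermKind,
    TermKindFilter,
    derive_curie,
    fallback_name,
)

log = logging.getLogger(__name__)

CACHE_FORMAT_MAJOR = 0  # bumped with the package major version

SKOS = rdflib.Namespace("http://www.w3.org/2004/02/skos/core#")
OBOINOWL = rdflib.Namespace("http://www.geneontology.org/formats/oboInOwl#")

LABEL_PROPERTIES = (RDFS.label, SKOS.prefLabel)
EXACT_SYNONYM_PROPERTIES = (
    OBOINOWL.hasExactSynonym,
    URIRef("http://ncicb.nci.nih.gov/xml/owl/EVS/Thesaurus.owl#P90"),
    URIRef("http://www.ebi.ac.uk/efo/alternative_term"),
)
BROAD_SYNONYM_PROPERTIES = (OBOINOWL.hasBroadSynonym,)
DEFINITION_PROPERTIES = (
    SKOS.definition,
    URIRef("http://purl.obolibrary.org/obo/IAO_0000115"),
)
OBSOLETE_CLASS = OBOINOWL.ObsoleteClass

PROPERTY_TYPES = (OWL.ObjectProperty, OWL.DatatypeProperty, OWL.AnnotationProperty)


def _parse_graph(source: str) -> rdflib.Graph:
    """Parse an RDF/XML or Turtle document from a path or URL."""
    if source.startswith(("http://", "https://")):
        try:
            with urllib.request.urlopen(source, timeout=60) as resp:
                data = resp.read()
        except urllib.error.HTTPError as e:
            raise OntologyError(
                f"failed to fetch ontology from {source}: HTTP {e.code}"
            ) from e
        except urllib.error.URLError as e:
            raise OntologyError(f"failed to fetch ontology from {source}: {e.reason}") from e
    else:
        path = Path(source)
        if not path.exists():
            raise OntologyError(f"ontology source not found: {source}")
        data = path.read_bytes()

    formats = ["xml", "turtle"]
    if source.endswith((".ttl", ".turtle", ".n3")):
        formats.reverse()
    errors = []
    for fmt in formats:
        graph = rdflib.Graph()
        try:
            graph.parse(data=data, format=fmt)
            return graph
        except Exception as e:  # rdflib raises assorted parser errors
            errors.append(f"{fmt}: {e}")
    raise OntologyError(
        f"could not parse ontology {source} as RDF/XML or Turtle ({'; '.join(errors)})"
    )


def _literals(graph: rdflib.Graph, subject: URIRef, props: Iterable[URIRef]) -> List[str]:
    """String values of the given annotation properties, deduplicated, in a
    deterministic order (property order, then lexicographic)."""
    out: List[str] = []
    seen: Set[str] = set()
    for prop in props:
        values = sorted(str(o) for o in graph.objects(subject, prop) if str(o).strip())
        for v in values:
            if v not in seen:
                seen.add(v)
                out.append(v)
    return out


def _is_deprecated(graph: rdflib.Graph, subject: URIRef) -> bool:
    for o in graph.objects(subject, OWL.deprecated):
        if str(o).strip().lower() == "true":
            return True
    for parent in graph.objects(subject, RDFS.subClassOf):
        if parent == OBSOLETE_CLASS:
            return True
    return False


def _extract_term(
    graph: rdflib.Graph,
    iri: URIRef,
    kind: TermKind,
    config: LoadConfig,
    index_counters: dict,
) -> OntologyTerm:
    term = OntologyTerm(
        iri=str(iri),
        curie=derive_curie(str(iri)),
        labels=_literals(graph, iri, LABEL_PROPERTIES),
        exact_synonyms=_literals(graph, iri, EXACT_SYNONYM_PROPERTIES),
        definitions=_literals(graph, iri, DEFINITION_PROPERTIES),
        deprecated=_is_deprecated(graph, iri),
        term_kind=kind,
    )
    if config.include_broad_synonyms:
        term.broad_synonyms = _literals(graph, iri, BROAD_SYNONYM_PROPERTIES)

    hierarchy_prop = RDFS.subClassOf if kind is TermKind.CLASS else RDFS.subPropertyOf
    for parent in graph.objects(iri, hierarchy_prop):
        if isinstance(parent, URIRef):
            if parent != OBSOLETE_CLASS and parent != OWL.Thing:
                term.parents.add(str(parent))
        else:
            # anonymous superclass (an OWL restriction): named parents only
            index_counters["anonymous"] += 1

    if not term.labels and not term.exact_synonyms:
        term.labels.append(fallback_name(str(iri)))
    return term


def load_ontology(
    source: str,
    config: Optional[LoadConfig] = None,
    reasoner: Optional[Callable[[rdflib.Graph], None]] = None,
) -> OntologyIndex:
    """Load a target ontology and build the term index.

    Parameters
    ----------
    source
        Local file path or http(s) URL of an OWL document in RDF/XML or
        Turtle serialization.
    config
        Extraction configuration; defaults to classes only, no broad
        synonyms, deprecated terms flagged but unmatchable, no reasoning.
    reasoner
        Optional hook invoked on the parsed graph before extraction when
        ``config.apply_reasoning`` is set; it may assert additional
        ``rdfs:subClassOf`` edges (e.g. from an external OWL reasoner).

    Raises
    ------
    OntologyError
        On unreadable/unparseable sources or when no terms survive the
        configured filters.
    """
    config = config or LoadConfig()
    graph = _parse_graph(source)
    if config.apply_reasoning and reasoner is not None:
        reasoner(graph)

    counters = {"anonymous": 0}
    terms: Dict[str, OntologyTerm] = {}

    wanted_kinds = []
    if config.term_kind_filter in (TermKindFilter.CLASSES, TermKindFilter.BOTH):
        wanted_kinds.append(TermKind.CLASS)
    if config.term_kind_filter in (TermKindFilter.PROPERTIES, TermKindFilter.BOTH):
        wanted_kinds.append(TermKind.PROPERTY)

    def in_base(iri: URIRef) -> bool:
        if not config.base_iris:
            return True
        return any(str(iri).startswith(p) for p in config.base_iris)

    if TermKind.CLASS in wanted_kinds:
        for s in graph.subjects(RDF.type, OWL.Class):
            if isinstance(s, URIRef) and s != OWL.Thing and s != OBSOLETE_CLASS and in_base(s):
                terms[str(s)] = _extract_term(graph, s, TermKind.CLASS, config, counters)
    if TermKind.PROPERTY in wanted_kinds:
        for ptype in PROPERTY_TYPES:
            for s in graph.subjects(RDF.type, ptype):
                if isinstance(s, URIRef) and str(s) not in terms and in_base(s):
                    terms[str(s)] = _extract_term(graph, s, TermKind.PROPERTY, config, counters)

    if not terms:
        raise OntologyError(f"no terms extracted from {source}")

    # children are the inverse of the asserted parent links
    for term in terms.values():
        for p in term.parents:
            if p in terms:
                terms[p].children.add(term.iri)

    # instances: individuals typed with a class in the index
    class_iris = {t.iri for t in terms.values() if t.term_kind is TermKind.CLASS}
    for s, o in graph.subject_objects(RDF.type):
        if isinstance(s, URIRef) and isinstance(o, URIRef) and str(o) in class_iris:
            if str(s) not in terms and (s, RDF.type, OWL.Class) not in graph:
                terms[str(o)].instances.add(str(s))

    ontology_iri = ""
    version = ""
    for onto in graph.subjects(RDF.type, OWL.Ontology):
        ontology_iri = str(onto)
        for v in graph.objects(onto, OWL.versionInfo):
            version = str(v)
        for v in graph.objects(onto, OWL.versionIRI):
            version = version or str(v)
        break

    index = OntologyIndex(
        source=source,
        terms=terms,
        load_config=config,
        ontology_iri=ontology_iri,
        version=version,
        skipped_anonymous=counters["anonymous"],
    )
    if counters["anonymous"]:
        log.info("skipped %d anonymous superclass expressions", counters["anonymous"])
    if index.dropped_dangling:
        log.warning("dropped %d dangling hierarchy references", index.dropped_dangling)
    return index


def ancestors(index: OntologyIndex, iri: str) -> frozenset:
    """Transitive closure of direct parents of ``iri`` (cached, cycle-safe)."""
    return index.ancestors(iri)


# --------------------------------------------------------------------------
# Cache

_METADATA_FILE = "metadata.json"
_TERMS_FILE = "terms.json"


def save_cache(index: OntologyIndex, directory: str | Path) -> Path:
    """Serialize an index to ``directory`` for later :func:`load_cache`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "cache_format_major": CACHE_FORMAT_MAJOR,
        "source": index.source,
        "ontology_iri": index.ontology_iri,
        "version": index.version,
        "load_config": index.load_config.to_dict(),
        "skipped_anonymous": index.skipped_anonymous,
        "dropped_dangling": index.dropped_dangling,
    }
    (directory / _METADATA_FILE).write_text(json.dumps(meta, indent=1))
    rows = []
    for iri in sorted(index.terms):
        t = index.terms[iri]
        rows.append(
            {
                "iri": t.iri,
                "curie": t.curie,
                "labels": t.labels,
                "exact_synonyms": t.exact_synonyms,
                "broad_synonyms": t.broad_synonyms,
                "definitions": t.definitions,
                "parents": sorted(t.parents),
                "children": sorted(t.children),
                "instances": sorted(t.instances),
                "deprecated": t.deprecated,
                "term_kind": t.term_kind.value,
            }
        )
    (directory / _TERMS_FILE).write_text(json.dumps(rows, indent=0))
    return directory


def load_cache(directory: str | Path) -> OntologyIndex:
    """Rebuild an index from a directory written by :func:`save_cache`."""
    directory = Path(directory)
    meta_path = directory / _METADATA_FILE
    terms_path = directory / _TERMS_FILE
    if not meta_path.exists() or not terms_path.exists():
        raise OntologyError(f"missing cache in {directory}")
    meta = json.loads(meta_path.read_text())
    if meta.get("cache_format_major") != CACHE_FORMAT_MAJOR:
        raise OntologyError(
            f"cache in {directory} was written by an incompatible version "
            f"(format {meta.get('cache_format_major')}, expected {CACHE_FORMAT_MAJOR}); "
            "please re-cache the ontology"
        )
    terms: Dict[str, OntologyTerm] = {}
    for row in json.loads(terms_path.read_text()):
        terms[row["iri"]] = OntologyTerm(
            iri=row["iri"],
            curie=row["curie"],
            labels=list(row["labels"]),
            exact_synonyms=list(row["exact_synonyms"]),
            broad_synonyms=list(row["broad_synonyms"]),
            definitions=list(row["definitions"]),
            parents=set(row["parents"]),
            children=set(row["children"]),
            instances=set(row["instances"]),
            deprecated=row["deprecated"],
            term_kind=TermKind(row["term_kind"]),
        )
    return OntologyIndex(
        source=meta["source"],
        terms=terms,
        load_config=LoadConfig.from_dict(meta["load_config"]),
        ontology_iri=meta["ontology_iri"],
        version=meta["version"],
        skipped_anonymous=meta.get("skipped_anonymous", 0),
    )
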