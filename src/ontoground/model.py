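"""Core domain types: ontology terms, the processed ontology index, load configuration.

An :class:`OntologyIndex` is the in-memory form of a target ontology after
extraction: a map from term IRI to :class:`OntologyTerm` carrying the names,
definitions and hierarchy links the mappers and the categorizer need, plus a
lazily built ancestor closure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple


class TermKind(str, Enum):
    CLASS = "class"
    PROPERTY = "property"


class TermKindFilter(str, Enum):
    CLASSES = "classes"
    PROPERTIES = "properties"
    BOTH = "both"


class OntologyError(Exception):
    """Fatal problem loading, caching or querying an ontology."""


@dataclass
class OntologyTerm:
    """One controlled term of an ontology.

    ``labels`` and ``exact_synonyms`` together form the term's matchable
    names; a term with neither receives a fallback name derived from its IRI
    local fragment at load time, so ``labels + exact_synonyms`` is never
    empty in a loaded index.
    """

    iri: str
    curie: str = ""
    labels: List[str] = field(default_factory=list)
    exact_synonyms: List[str] = field(default_factory=list)
    broad_synonyms: List[str] = field(default_factory=list)
    definitions: List[str] = field(default_factory=list)
    parents: Set[str] = field(default_factory=set)
    children: Set[str] = field(default_factory=set)
    instances: Set[str] = field(default_factory=set)
    deprecated: bool = False
    term_kind: TermKind = TermKind.CLASS

    @property
    def display_label(self) -> str:
        """First label in document order, or the first synonym as fallback."""
        if self.labels:
            return self.labels[0]
        if self.exact_synonyms:
            return self.exact_synonyms[0]
        return self.iri

    @property
    def identifier(self) -> str:
        """CURIE when derivable, else the full IRI (what output tables print)."""
        return self.curie or self.iri


@dataclass(frozen=True)
class LoadConfig:
    """Configuration for ontology extraction.

    Defaults: map to classes only, no broad synonyms, exclude deprecated
    terms from the matchable set, no reasoning, no IRI restriction.
    """

    term_kind_filter: TermKindFilter = TermKindFilter.CLASSES
    include_broad_synonyms: bool = False
    include_deprecated: bool = False
    apply_reasoning: bool = False
    base_iris: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "term_kind_filter": self.term_kind_filter.value,
            "include_broad_synonyms": self.include_broad_synonyms,
            "include_deprecated": self.include_deprecated,
            "apply_reasoning": self.apply_reasoning,
            "base_iris": list(self.base_iris),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LoadConfig":
        return cls(
            term_kind_filter=TermKindFilter(d["term_kind_filter"]),
            include_broad_synonyms=d["include_broad_synonyms"],
            include_deprecated=d["include_deprecated"],
            apply_reasoning=d["apply_reasoning"],
            base_iris=tuple(d["base_iris"]),
        )


_OBO_PURL = re.compile(r"^http://purl\.obolibrary\.org/obo/([A-Za-z]+)_([A-Za-z0-9]+)$")
_EFO_IRI = re.compile(r"^http://www\.ebi\.ac\.uk/efo/(EFO)_([A-Za-z0-9]+)$")


def derive_curie(iri: str) -> str:
    """Compact identifier for OBO-PURL and EFO IRI patterns; empty otherwise.

    ``http://purl.obolibrary.org/obo/MONDO_0004975`` -> ``MONDO:0004975``;
    ``http://www.ebi.ac.uk/efo/EFO_0000249`` -> ``EFO:0000249``.
    """
    for pat in (_OBO_PURL, _EFO_IRI):
        m = pat.match(iri)
        if m:
            return f"{m.group(1)}:{m.group(2)}"
    return ""


_CAMEL_SPLIT = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")


def fallback_name(iri: str) -> str:
    """Human-ish name from an IRI local fragment: '_' and camelCase to spaces."""
    local = iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    local = local.replace("_", " ")
    local = _CAMEL_SPLIT.sub(" ", local)
    return " ".join(local.split())


@dataclass
class OntologyIndex:
    """A processed target ontology: terms plus provenance and closure cache."""

    source: str
    terms: Dict[str, OntologyTerm]
    load_config: LoadConfig = field(default_factory=LoadConfig)
    ontology_iri: str = ""
    version: str = ""
    dropped_dangling: int = 0
    skipped_anonymous: int = 0
    _closure: Dict[str, FrozenSet[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._prune_dangling()

    def _prune_dangling(self) -> None:
        """Drop hierarchy links pointing outside the index, counting them."""
        known = self.terms.keys()
        for term in self.terms.values():
            for attr in ("parents", "children", "instances"):
                refs: Set[str] = getattr(term, attr)
                dangling = {r for r in refs if r not in known}
                if dangling:
                    self.dropped_dangling += len(dangling)
                    refs.difference_update(dangling)

    def ancestors(self, iri: str) -> FrozenSet[str]:
        """Transitive closure over direct parents of ``iri``.

        Cycle-safe fixpoint; the term itself is included only if it lies on
        a subclass cycle. Results are cached per index.
        """
        if iri not in self.terms:
            raise OntologyError(f"unknown IRI: {iri}")
        cached = self._closure.get(iri)
        if cached is not None:
            return cached
        seen: Set[str] = set()
        stack = list(self.terms[iri].parents)
        while stack:
            p = stack.pop()
            if p in seen:
                continue
            seen.add(p)
            stack.extend(self.terms[p].parents - seen)
        result = frozenset(seen)
        self._closure[iri] = result
        return result

    def matchable_terms(self) -> List[OntologyTerm]:
        """Terms eligible for matching: excludes deprecated unless configured."""
        if self.load_config.include_deprecated:
            return list(self.terms.values())
        return [t for t in self.terms.values() if not t.deprecated]

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, iri: str) -> bool:
        return iri in self.terms
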