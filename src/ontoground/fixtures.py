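"""Synthetic OWL ontologies and query sets with ground truth.

Everything here exists so the loader, mappers and categorizer can be
exercised offline against known answers.  :func:`generate_toy_ontology`
emits a rooted tree/DAG of classes as RDF/XML with labels, exact/broad
synonyms, definitions and deprecation flags drawn from a seeded
pseudo-biomedical vocabulary; :func:`corrupt_label` applies seeded
character edits to build typo'd queries; :func:`table2_mirror_ontology`
is a small hand-written disease ontology whose hierarchy encodes known
Same/MoreSpecific/MoreGeneral/Sibling/Unrelated relationships between
real-world disease terms.

The RDF/XML is produced by direct string templating rather than a graph
serializer so that an identical :class:`FixtureSpec` yields byte-identical
documents.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple
from xml.sax.saxutils import escape

from .categorize import MappingCategory

TOY_PREFIX = "http://purl.obolibrary.org/obo/TOY_"

# Pseudo-biomedical vocabulary: word-shaped, non-degenerate n-gram statistics.
_STEM_SYLLABLES = [
    "car", "neu", "der", "hep", "nephr", "ost", "myel", "gastr", "bronch",
    "cephal", "angi", "arthr", "cyt", "fibr", "gli", "lymph", "melan", "oste",
]
_STEM_TAILS = ["oma", "itis", "osis", "opathy", "algia", "emia", "plasia"]
_MODIFIERS = [
    "chronic", "acute", "juvenile", "familial", "diffuse", "focal",
    "recurrent", "severe", "atypical", "congenital", "idiopathic", "systemic",
]
_ANATOMY = [
    "of the liver", "of the kidney", "of the lung", "of the skin",
    "of the heart", "of the spine", "of the retina", "of bone",
]
_REAL_TOKENS = [
    "carcinoma", "lymphoma", "dermatitis", "nephritis", "anemia", "asthma",
    "fibrosis", "melanoma", "neuropathy", "sarcoma", "stenosis", "thrombosis",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated toy ontology; identical specs give
    byte-identical documents."""

    n_terms: int = 50
    max_children: int = 4
    synonym_rate: float = 0.5
    deprecated_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if self.max_children < 1:
            raise ValueError("max_children must be >= 1")
        for name in ("synonym_rate", "deprecated_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class TermTruth:
    iri: str
    labels: List[str]
    exact_synonyms: List[str]
    broad_synonyms: List[str]
    definitions: List[str]
    parents: List[str]
    deprecated: bool


@dataclass
class QueryTruth:
    query: str
    true_iri: str
    n_edits: int


@dataclass
class GroundTruth:
    """Exactly what the generator wrote, for extraction-completeness checks."""

    terms: Dict[str, TermTruth] = field(default_factory=dict)
    queries: List[QueryTruth] = field(default_factory=list)

    def matchable_iris(self) -> List[str]:
        return [t.iri for t in self.terms.values() if not t.deprecated]


def _make_name(rng: random.Random, used: Set[str]) -> str:
    """One unique multi-word pseudo-biomedical name."""
    for _ in range(1000):
        parts = []
        if rng.random() < 0.7:
            parts.append(rng.choice(_MODIFIERS))
        if rng.random() < 0.4:
            parts.append(rng.choice(_REAL_TOKENS))
        else:
            parts.append(rng.choice(_STEM_SYLLABLES) + rng.choice(_STEM_TAILS))
        if rng.random() < 0.5:
            parts.append(rng.choice(_ANATOMY))
        name = " ".join(parts)
        if name not in used:
            used.add(name)
            return name
    raise RuntimeError("vocabulary exhausted; lower n_terms")  # pragma: no cover


_XML_HEAD = """<?xml version="1.0" encoding="UTF-8"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
         xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#"
         xmlns:owl="http://www.w3.org/2002/07/owl#"
         xmlns:skos="http://www.w3.org/2004/02/skos/core#"
         xmlns:oboInOwl="http://www.geneontology.org/formats/oboInOwl#">
"""


def _class_xml(t: TermTruth) -> str:
    lines = [f'  <owl:Class rdf:about="{escape(t.iri)}">']
    for label in t.labels:
        lines.append(f"    <rdfs:label>{escape(label)}</rdfs:label>")
    for syn in t.exact_synonyms:
        lines.append(
            f"    <oboInOwl:hasExactSynonym>{escape(syn)}</oboInOwl:hasExactSynonym>"
        )
    for syn in t.broad_synonyms:
        lines.append(
            f"    <oboInOwl:hasBroadSynonym>{escape(syn)}</oboInOwl:hasBroadSynonym>"
        )
    for d in t.definitions:
        lines.append(f"    <skos:definition>{escape(d)}</skos:definition>")
    for p in t.parents:
        lines.append(f'    <rdfs:subClassOf rdf:resource="{escape(p)}"/>')
    if t.deprecated:
        lines.append(
            '    <owl:deprecated rdf:datatype='
            '"http://www.w3.org/2001/XMLSchema#boolean">true</owl:deprecated>'
        )
    lines.append("  </owl:Class>")
    return "\n".join(lines)


def generate_toy_ontology(spec: FixtureSpec) -> Tuple[str, GroundTruth]:
    """Build a seeded toy ontology; returns (RDF/XML document, ground truth).

    The hierarchy is a rooted DAG: every non-root class gets one parent
    among earlier classes with spare child capacity, and with small
    probability a second parent (producing diamonds).  Labels are globally
    unique, and synonyms never collide with any label, so the refind
    property (a term's own label retrieves that term at rank 1, score 1)
    holds by construction on uncorrupted queries.
    """
    rng = random.Random(spec.seed)
    used_names: Set[str] = set()
    truth = GroundTruth()
    iris = [f"{TOY_PREFIX}{i:07d}" for i in range(spec.n_terms)]
    child_count = {iri: 0 for iri in iris}

    for i, iri in enumerate(iris):
        label = _make_name(rng, used_names)
        synonyms: List[str] = []
        broad: List[str] = []
        if rng.random() < spec.synonym_rate:
            for _ in range(rng.randint(1, 2)):
                synonyms.append(_make_name(rng, used_names))
        if rng.random() < spec.synonym_rate * 0.5:
            broad.append(_make_name(rng, used_names))
        parents: List[str] = []
        if i > 0:
            candidates = [p for p in iris[:i] if child_count[p] < spec.max_children]
            if not candidates:
                candidates = [iris[0]]
            parent = rng.choice(candidates)
            parents.append(parent)
            child_count[parent] += 1
            if i > 1 and rng.random() < 0.15:
                second = rng.choice([p for p in iris[:i] if p != parent])
                parents.append(second)
                child_count[second] += 1
        deprecated = i > 0 and rng.random() < spec.deprecated_rate
        truth.terms[iri] = TermTruth(
            iri=iri,
            labels=[label],
            exact_synonyms=sorted(synonyms),
            broad_synonyms=sorted(broad),
            definitions=[f"A synthetic condition called {label}."],
            parents=sorted(parents),
            deprecated=deprecated,
        )

    truth.queries = [
        QueryTruth(query=t.labels[0], true_iri=t.iri, n_edits=0)
        for t in truth.terms.values()
        if not t.deprecated
    ]

    doc = [_XML_HEAD]
    doc.append(
        f'  <owl:Ontology rdf:about="http://example.org/ontoground/toy-{spec.seed}">\n'
        f"    <owl:versionInfo>spec-seed-{spec.seed}</owl:versionInfo>\n"
        "  </owl:Ontology>"
    )
    for iri in iris:
        doc.append(_class_xml(truth.terms[iri]))
    doc.append("</rdf:RDF>\n")
    return "\n".join(doc), truth


def corrupt_label(label: str, n_edits: int, seed: int) -> str:
    """Apply ``n_edits`` seeded single-character edits to ``label``.

    Each edit is a substitution (with a different character), insertion or
    deletion at a seeded position, so the result differs from the input by
    Levenshtein distance at most ``n_edits``; ``n_edits=0`` is identity.
    """
    if n_edits < 0:
        raise ValueError("n_edits must be >= 0")
    if len(label) <= n_edits:
        raise ValueError(f"label {label!r} too short for {n_edits} edits")
    if n_edits == 0:
        return label
    rng = random.Random(seed)
    chars = list(label)
    alphabet = string.ascii_lowercase
    for _ in range(n_edits):
        op = rng.choice(("substitute", "insert", "delete"))
        if op == "substitute":
            pos = rng.randrange(len(chars))
            old = chars[pos]
            chars[pos] = rng.choice([c for c in alphabet if c != old])
        elif op == "insert":
            pos = rng.randrange(len(chars) + 1)
            chars.insert(pos, rng.choice(alphabet))
        else:
            pos = rng.randrange(len(chars))
            del chars[pos]
    return "".join(chars)


def generate_corrupted_queries(
    truth: GroundTruth, n_edits: int, seed: int
) -> List[QueryTruth]:
    """One typo'd query per matchable term, edits seeded per term."""
    out = []
    for i, q in enumerate(truth.queries):
        out.append(
            QueryTruth(
                query=corrupt_label(q.query, n_edits, seed + i),
                true_iri=q.true_iri,
                n_edits=n_edits,
            )
        )
    return out


# --------------------------------------------------------------------------
# Hand-written disease ontology mirroring known category relationships.

_OBO = "http://purl.obolibrary.org/obo/"
_EFO = "http://www.ebi.ac.uk/efo/"


def _t(
    iri: str,
    label: str,
    parents: Sequence[str] = (),
    synonyms: Sequence[str] = (),
    deprecated: bool = False,
) -> TermTruth:
    return TermTruth(
        iri=iri,
        labels=[label],
        exact_synonyms=list(synonyms),
        broad_synonyms=[],
        definitions=[],
        parents=list(parents),
        deprecated=deprecated,
    )


def table2_mirror_ontology() -> Tuple[str, List[Tuple[str, str, str, MappingCategory]]]:
    """A ~17-class disease ontology with known hierarchical relationships.

    Returns the RDF/XML document plus expected-category rows as
    ``(input_text, tool term IRI, benchmark term IRI, category)``: e.g. a
    mapping to "allergic rhinitis" judged against benchmark "seasonal
    allergic rhinitis" is MoreGeneral, "uremia" against "kidney failure" is
    MoreSpecific, "chronic bronchitis" against "emphysema" (common direct
    parent: lung disease) is Sibling, and the deprecated duplicate
    "Alzheimer's disease" term is hierarchically Unrelated to its
    non-deprecated replacement.
    """
    disease = f"{_EFO}EFO_0000408"
    resp = f"{_EFO}EFO_0009690"
    rhinitis = f"{_EFO}EFO_0005854"
    seasonal = f"{_EFO}EFO_0003956"
    lung = f"{_OBO}MONDO_0005275"
    bronchitis = f"{_EFO}EFO_0006505"
    emphysema = f"{_EFO}EFO_0000464"
    kidney_dis = f"{_EFO}EFO_0003086"
    kidney_failure = f"{_EFO}EFO_1002048"
    uremia = f"{_EFO}EFO_1001226"
    pain = f"{_EFO}EFO_0003843"
    chronic_pain = f"{_OBO}HP_0012532"
    thyroid_dis = f"{_EFO}EFO_1000627"
    thyroiditis = f"{_OBO}MONDO_0004126"
    alzheimer = f"{_OBO}MONDO_0004975"
    alzheimer_old = f"{_EFO}EFO_0000249"
    mi = f"{_OBO}MONDO_0005068"

    terms = [
        _t(disease, "disease"),
        _t(resp, "respiratory system disease", [disease]),
        _t(rhinitis, "allergic rhinitis", [resp], synonyms=["hayfever"]),
        _t(seasonal, "seasonal allergic rhinitis", [rhinitis]),
        _t(lung, "lung disease", [resp]),
        _t(bronchitis, "chronic bronchitis", [lung]),
        _t(emphysema, "emphysema", [lung]),
        _t(kidney_dis, "kidney disease", [disease]),
        _t(kidney_failure, "kidney failure", [kidney_dis], synonyms=["renal failure"]),
        _t(uremia, "uremia", [kidney_failure]),
        _t(pain, "pain", [disease]),
        _t(chronic_pain, "chronic pain", [pain]),
        _t(thyroid_dis, "thyroid disease", [disease]),
        _t(thyroiditis, "thyroiditis", [thyroid_dis]),
        _t(alzheimer, "Alzheimer disease", [disease], synonyms=["Alzheimer's disease"]),
        _t(alzheimer_old, "Alzheimer's disease (obsolete)", deprecated=True),
        _t(mi, "myocardial infarction", [disease], synonyms=["heart attack"]),
    ]

    expected = [
        ("Hayfever or allergic rhinitis", rhinitis, seasonal, MappingCategory.MORE_GENERAL),
        ("General pain for 3+ months", pain, chronic_pain, MappingCategory.MORE_GENERAL),
        ("Uremia", uremia, kidney_failure, MappingCategory.MORE_SPECIFIC),
        ("Thyroiditis", thyroiditis, thyroid_dis, MappingCategory.MORE_SPECIFIC),
        ("Emphysema/chronic bronchitis", bronchitis, emphysema, MappingCategory.SIBLING),
        ("Alzheimer's disease", alzheimer, alzheimer_old, MappingCategory.UNRELATED),
    ]

    doc = [_XML_HEAD]
    doc.append(
        '  <owl:Ontology rdf:about="http://example.org/ontoground/table-mirror">\n'
        "    <owl:versionInfo>1.0</owl:versionInfo>\n"
        "  </owl:Ontology>"
    )
    for t in terms:
        doc.append(_class_xml(t))
    doc.append("</rdf:RDF>\n")
    return "\n".join(doc), expected
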