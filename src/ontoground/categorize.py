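"""Hierarchical categorization of tool mappings against benchmark mappings.

Given a tool-generated mapping T and a human-verified benchmark mapping H
for the same input text, T is placed in exactly one of five categories
using the ontology class hierarchy:

* ``Same`` — T and H are the same term.
* ``MoreSpecific`` — T is a (transitive) subclass of H.
* ``MoreGeneral`` — T is a (transitive) superclass of H.
* ``Sibling`` — T and H share a direct superclass.
* ``Unrelated`` — none of the above.

Precedence runs in that order, which resolves pairs satisfying several
clauses at once (e.g. a direct parent that is also a co-child in a diamond
counts as MoreGeneral, not Sibling).  Entailment is approximated by the
transitive closure over asserted subclass edges (plus any edges a reasoning
pre-step added at load time).

Benchmark sets are first reduced to unambiguous entries: only inputs with
exactly one distinct benchmark term are kept, since a singular mapping is
the only unambiguous statement of the intended term.  Benchmark entries
pointing at deprecated terms are retained but flagged, as mismatches
against obsolete terms are themselves informative.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .mapping_io import MappingTable
from .model import OntologyError, OntologyIndex


class MappingCategory(str, Enum):
    SAME = "Same"
    MORE_SPECIFIC = "MoreSpecific"
    MORE_GENERAL = "MoreGeneral"
    SIBLING = "Sibling"
    UNRELATED = "Unrelated"


CATEGORY_ORDER = [
    MappingCategory.SAME,
    MappingCategory.MORE_SPECIFIC,
    MappingCategory.MORE_GENERAL,
    MappingCategory.SIBLING,
    MappingCategory.UNRELATED,
]


@dataclass(frozen=True)
class BenchmarkEntry:
    """One human-verified mapping: input text and its benchmark term H."""

    input_text: str
    benchmark_iri: str
    source_label: Optional[str] = None


@dataclass
class ComparisonReport:
    """Aggregate of categorizing every tool mapping against its benchmark."""

    counts: Dict[MappingCategory, int] = field(default_factory=dict)
    percents: Dict[MappingCategory, float] = field(default_factory=dict)
    pairs: List[Tuple[str, str, str, MappingCategory]] = field(default_factory=list)
    excluded_multi_mapping: int = 0
    excluded_unresolvable: int = 0
    unmapped_by_tool: int = 0
    deprecated_benchmark: int = 0

    @property
    def n_categorized(self) -> int:
        return sum(self.counts.values())

    def summary_rows(self) -> List[Tuple[str, int, float]]:
        """(category, count, percent) rows in the conventional order."""
        return [
            (c.value, self.counts.get(c, 0), self.percents.get(c, 0.0))
            for c in CATEGORY_ORDER
        ]


def filter_unambiguous(
    benchmark: Iterable[Tuple[str, str]],
) -> Tuple[List[BenchmarkEntry], int]:
    """Keep only inputs mapped to exactly one distinct benchmark term.

    Duplicate (input, term) assertions collapse to one entry; an input
    asserted with two or more distinct terms is ambiguous and excluded.
    Returns the kept entries (input order of first appearance) and the
    number of excluded inputs.
    """
    targets: Dict[str, set] = {}
    order: List[str] = []
    for text, iri in benchmark:
        if text not in targets:
            targets[text] = set()
            order.append(text)
        targets[text].add(iri)
    kept = [
        BenchmarkEntry(input_text=t, benchmark_iri=next(iter(targets[t])))
        for t in order
        if len(targets[t]) == 1
    ]
    excluded = sum(1 for t in order if len(targets[t]) > 1)
    return kept, excluded


def categorize_pair(index: OntologyIndex, t_iri: str, h_iri: str) -> MappingCategory:
    """Categorize tool term T against benchmark term H (precedence above)."""
    if t_iri not in index:
        raise OntologyError(f"unknown IRI: {t_iri}")
    if h_iri not in index:
        raise OntologyError(f"unknown IRI: {h_iri}")
    if t_iri == h_iri:
        return MappingCategory.SAME
    if h_iri in index.ancestors(t_iri):
        return MappingCategory.MORE_SPECIFIC
    if t_iri in index.ancestors(h_iri):
        return MappingCategory.MORE_GENERAL
    if index.terms[t_iri].parents & index.terms[h_iri].parents:
        return MappingCategory.SIBLING
    return MappingCategory.UNRELATED


def _resolve_iri(index: OntologyIndex, identifier: str) -> Optional[str]:
    """Accept either a full IRI or a CURIE known to the index."""
    if identifier in index:
        return identifier
    for term in index.terms.values():
        if term.curie and term.curie == identifier:
            return term.iri
    return None


def compare_mapping_sets(
    tool: MappingTable,
    benchmark: Sequence[BenchmarkEntry],
    index: OntologyIndex,
) -> ComparisonReport:
    """Categorize the tool's top-ranked mapping against each benchmark entry.

    Inputs the tool left unmapped are counted separately (``unmapped_by_tool``),
    not forced into Unrelated; benchmark entries whose term cannot be
    resolved in the index are tallied in ``excluded_unresolvable``.
    """
    report = ComparisonReport()
    top = tool.top_ranked()
    counter: Counter = Counter()
    for entry in benchmark:
        h_iri = _resolve_iri(index, entry.benchmark_iri)
        if h_iri is None:
            report.excluded_unresolvable += 1
            continue
        if index.terms[h_iri].deprecated:
            report.deprecated_benchmark += 1
        row = top.get(entry.input_text)
        if row is None:
            report.unmapped_by_tool += 1
            continue
        t_iri = _resolve_iri(index, row.term_iri)
        if t_iri is None:
            report.excluded_unresolvable += 1
            continue
        category = categorize_pair(index, t_iri, h_iri)
        counter[category] += 1
        report.pairs.append((entry.input_text, t_iri, h_iri, category))
    report.counts = dict(counter)
    total = sum(counter.values())
    report.percents = {
        c: (100.0 * n / total if total else 0.0) for c, n in counter.items()
    }
    return report


def read_benchmark(path, index: Optional[OntologyIndex] = None) -> List[BenchmarkEntry]:
    """Load a benchmark set from SSSOM-style TSV or a 2-column CSV/TSV
    (input_text, iri), then apply the exactly-one-mapping filter."""
    from .mapping_io import InputError, read_mapping_table

    try:
        table = read_mapping_table(path)
        pairs = [(row.source.text, row.term_iri) for row in table.rows]
    except InputError:
        import pandas as pd

        frame = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
        if frame.shape[1] < 2:
            raise
        pairs = [
            (str(r.iloc[0]).strip(), str(r.iloc[1]).strip()) for _, r in frame.iterrows()
        ]
    kept, _ = filter_unambiguous(pairs)
    return kept
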