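"""End-to-end mapping orchestration and tabular input/output.

:func:`map_terms` is the single entry point: it takes source terms (raw
strings, a parsed list, or a file), a target ontology (path, URL, cache
directory, already-loaded index — or a repository acronym for the web
annotator mappers), and mapper/load configuration, and returns a
:class:`MappingTable` that can be written to CSV/TSV and read back.

The output schema is fixed: ``#``-prefixed ``key: value`` metadata lines,
then a header row and one data row per mapping, with columns Source Term
ID, Source Term, Mapped Term Label, Mapped Term CURIE, Mapped Term IRI,
Mapping Score (6 decimals), Mapper, Mapping Type, Tags.  Source terms that
matched nothing above the score threshold appear with empty mapped fields
when ``include_unmapped`` is set.  SSSOM-style TSV (subject_id/object_id
columns) is also accepted on read, yielding mappings tagged
``mapper="external"``.
"""

from __future__ import annotations

import csv
import datetime
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .mappers import (
    MapperConfig,
    RawMatch,
    SYNTACTIC_METRICS,
    build_name_corpus,
    syntactic_map,
    tfidf_map,
)
from .model import LoadConfig, OntologyIndex, derive_curie
from .ontology import load_cache, load_ontology


class InputError(Exception):
    """Unusable source-term or mapping-table input."""


@dataclass(frozen=True)
class SourceTerm:
    """One free-text input to be mapped."""

    text: str
    source_id: Optional[str] = None
    tags: tuple = ()

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise InputError("source term text must be non-empty")


@dataclass
class TermMapping:
    """One (source term -> ontology term) mapping in the output table."""

    source: SourceTerm
    term_iri: str
    term_curie: str
    term_label: str
    score: float
    mapper: str
    mapping_type: str = "Exact"  # Exact | Broad | Narrow (skos:mappingRelation)


@dataclass
class MappingTable:
    """Mapping results: rows grouped by source in input order, descending
    score within a source, plus the sources left unmapped."""

    rows: List[TermMapping] = field(default_factory=list)
    unmapped: List[SourceTerm] = field(default_factory=list)
    unmapped_reasons: Dict[str, str] = field(default_factory=dict)
    metadata: Dict[str, str] = field(default_factory=dict)

    def top_ranked(self) -> Dict[str, TermMapping]:
        """Best mapping per source text (first row of each source group)."""
        best: Dict[str, TermMapping] = {}
        for row in self.rows:
            best.setdefault(row.source.text, row)
        return best


def read_source_terms(
    path: Union[str, Path],
    delimiter: Optional[str] = None,
    column: Optional[Union[str, int]] = None,
    id_column: Optional[Union[str, int]] = None,
) -> List[SourceTerm]:
    """Read source terms from a line-separated file or a delimited table.

    Line mode (no ``delimiter``): one term per non-empty line.  Table mode:
    terms come from ``column`` (name or 0-based index; defaults to the first
    column) and optional identifiers from ``id_column``.  Input order is
    preserved; surrounding whitespace is trimmed.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"source file not found: {path}")

    if delimiter is None:
        terms = [
            SourceTerm(text=line.strip())
            for line in path.read_text(encoding="utf-8").splitlines()
            if line.strip()
        ]
        if not terms:
            raise InputError(f"no source terms in {path}")
        return terms

    frame = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)

    def resolve(col: Union[str, int], what: str) -> str:
        if isinstance(col, int):
            if col >= len(frame.columns):
                raise InputError(
                    f"{what} index {col} out of range; columns: {list(frame.columns)}"
                )
            return frame.columns[col]
        if col not in frame.columns:
            raise InputError(f"{what} {col!r} not found; columns: {list(frame.columns)}")
        return col

    term_col = resolve(column if column is not None else 0, "column")
    id_col = resolve(id_column, "id column") if id_column is not None else None

    terms = []
    for _, row in frame.iterrows():
        text = str(row[term_col]).strip()
        if not text:
            continue
        sid = str(row[id_col]).strip() if id_col else None
        terms.append(SourceTerm(text=text, source_id=sid or None))
    if not terms:
        raise InputError(f"no source terms in {path}")
    return terms


def _coerce_sources(sources: Sequence[Union[str, SourceTerm]]) -> List[SourceTerm]:
    return [s if isinstance(s, SourceTerm) else SourceTerm(text=s) for s in sources]


def _resolve_ontology(
    ontology: Union[str, Path, OntologyIndex], load_config: LoadConfig
) -> OntologyIndex:
    if isinstance(ontology, OntologyIndex):
        return ontology
    path = Path(str(ontology))
    if path.is_dir():
        return load_cache(path)
    return load_ontology(str(ontology), load_config)


def map_terms(
    sources: Sequence[Union[str, SourceTerm]],
    ontology: Union[str, Path, OntologyIndex],
    mapper_config: Optional[MapperConfig] = None,
    load_config: Optional[LoadConfig] = None,
    include_unmapped: bool = True,
    **web_kwargs,
) -> MappingTable:
    """Map source terms to an ontology and assemble the mapping table.

    ``ontology`` may be a local OWL path, a URL, a cache directory written
    by :func:`ontoground.ontology.save_cache`, an already-loaded
    :class:`OntologyIndex` — or, for the ``bioportal``/``zooma`` mappers,
    the repository acronym of the target ontology.  Extra keyword arguments
    are forwarded to the web mappers (api_key, transport, ...).

    Deterministic for the offline mappers: identical inputs and
    configuration produce identical tables.
    """
    mapper_config = mapper_config or MapperConfig()
    load_config = load_config or LoadConfig()
    source_terms = _coerce_sources(sources)
    texts = [s.text for s in source_terms]
    failures: Dict[int, str] = {}

    if mapper_config.mapper in ("bioportal", "zooma"):
        from . import web

        index = None
        if mapper_config.mapper == "bioportal":
            matches = web.bioportal_map(
                texts, str(ontology), mapper_config, failures=failures, **web_kwargs
            )
        else:
            matches = web.zooma_map(
                texts, str(ontology), mapper_config, failures=failures, **web_kwargs
            )
    else:
        index = _resolve_ontology(ontology, load_config)
        corpus = build_name_corpus(index, include_broad=load_config.include_broad_synonyms)
        if mapper_config.mapper == "tfidf":
            matches = tfidf_map(texts, corpus, mapper_config)
        elif mapper_config.mapper in SYNTACTIC_METRICS:
            matches = syntactic_map(texts, corpus, mapper_config)
        else:  # pragma: no cover - MapperConfig already validates
            raise ValueError(f"unknown mapper {mapper_config.mapper!r}")

    by_source: Dict[int, List[RawMatch]] = {}
    for m in matches:
        by_source.setdefault(m.source_index, []).append(m)

    table = MappingTable(
        metadata={
            "ontology": str(ontology) if index is None else index.source,
            "mapper": mapper_config.mapper,
            "ngram_size": str(mapper_config.ngram_size),
            "max_mappings": str(mapper_config.max_mappings),
            "min_score": repr(mapper_config.min_score),
            "version": __version__,
        }
    )
    for qi, st in enumerate(source_terms):
        source_matches = by_source.get(qi, [])
        if not source_matches:
            if include_unmapped:
                table.unmapped.append(st)
                if qi in failures:
                    table.unmapped_reasons[st.text] = failures[qi]
            continue
        for m in source_matches:
            if index is not None:
                term = index.terms[m.term_iri]
                label, curie = term.display_label, term.identifier
            else:
                label, curie = m.matched_name, derive_curie(m.term_iri) or m.term_iri
            table.rows.append(
                TermMapping(
                    source=st,
                    term_iri=m.term_iri,
                    term_curie=curie,
                    term_label=label,
                    score=m.score,
                    mapper=mapper_config.mapper,
                )
            )
    return table


COLUMNS = [
    "Source Term ID",
    "Source Term",
    "Mapped Term Label",
    "Mapped Term CURIE",
    "Mapped Term IRI",
    "Mapping Score",
    "Mapper",
    "Mapping Type",
    "Tags",
]


def write_mapping_table(
    table: MappingTable,
    path: Union[str, Path],
    format: str = "csv",
    timestamp: bool = True,
) -> Path:
    """Write a mapping table to CSV or TSV.

    Scores print with 6 decimal places.  With ``timestamp=False`` the
    output is byte-reproducible across runs of the same job.
    """
    if format not in ("csv", "tsv"):
        raise InputError(f"unknown format {format!r}; expected csv or tsv")
    path = Path(path)
    sep = "," if format == "csv" else "\t"
    buf = _stdio.StringIO()
    for key, value in table.metadata.items():
        buf.write(f"# {key}: {value}\n")
    if timestamp:
        buf.write(f"# timestamp: {datetime.datetime.now().isoformat()}\n")
    writer = csv.writer(buf, delimiter=sep, lineterminator="\n")
    writer.writerow(COLUMNS)
    for row in table.rows:
        writer.writerow(
            [
                row.source.source_id or "",
                row.source.text,
                row.term_label,
                row.term_curie,
                row.term_iri,
                f"{row.score:.6f}",
                row.mapper,
                row.mapping_type,
                ";".join(row.source.tags),
            ]
        )
    for st in table.unmapped:
        writer.writerow([st.source_id or "", st.text, "", "", "", "", "", "", ";".join(st.tags)])
    try:
        path.write_text(buf.getvalue(), encoding="utf-8")
    except OSError as e:
        raise InputError(f"cannot write mapping table to {path}: {e}") from e
    return path


SSSOM_COLUMNS = {"subject_id", "object_id"}


def read_mapping_table(path: Union[str, Path]) -> MappingTable:
    """Read a mapping table written by :func:`write_mapping_table`, or an
    SSSOM-style TSV with subject/object columns (``mapper="external"``)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"mapping table not found: {path}")
    metadata: Dict[str, str] = {}
    data_lines: List[str] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, v = body.split(":", 1)
                metadata[k.strip()] = v.strip()
            continue
        data_lines.append(line)
    if not data_lines:
        raise InputError(f"no header row in {path}")
    sep = "\t" if "\t" in data_lines[0] else ","
    frame = pd.read_csv(
        _stdio.StringIO("\n".join(data_lines)), sep=sep, dtype=str, keep_default_na=False
    )
    cols = set(frame.columns)

    table = MappingTable(metadata=metadata)
    if frame.empty:
        import warnings

        warnings.warn(f"mapping table {path} contains only a header")
    if set(COLUMNS[:6]).issubset(cols):
        for _, r in frame.iterrows():
            st = SourceTerm(
                text=r["Source Term"],
                source_id=r["Source Term ID"] or None,
                tags=tuple(t for t in r.get("Tags", "").split(";") if t),
            )
            if not r["Mapped Term IRI"]:
                table.unmapped.append(st)
                continue
            table.rows.append(
                TermMapping(
                    source=st,
                    term_iri=r["Mapped Term IRI"],
                    term_curie=r["Mapped Term CURIE"],
                    term_label=r["Mapped Term Label"],
                    score=float(r["Mapping Score"]),
                    mapper=r.get("Mapper", "") or "external",
                    mapping_type=r.get("Mapping Type", "") or "Exact",
                )
            )
        return table
    if SSSOM_COLUMNS.issubset(cols):
        for _, r in frame.iterrows():
            if not r["subject_id"] or not r["object_id"]:
                continue
            st = SourceTerm(
                text=r.get("subject_label", "") or r["subject_id"],
                source_id=r["subject_id"],
            )
            table.rows.append(
                TermMapping(
                    source=st,
                    term_iri=r["object_id"],
                    term_curie=r["object_id"] if ":" in r["object_id"] else "",
                    term_label=r.get("object_label", ""),
                    score=1.0,
                    mapper="external",
                )
            )
        return table
    raise InputError(
        f"unrecognized mapping table schema in {path}; columns found: {sorted(cols)}"
    )
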