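"""Remote annotator clients: BioPortal Annotator and Zooma.

These mappers call external REST services and therefore need network access
and (for BioPortal) an API key.  Both accept an injectable ``transport``
callable — ``transport(url) -> parsed JSON`` — so the request/scoring logic
is testable against recorded responses without any network traffic.

Scoring: BioPortal returns no confidence, so every annotation gets score
1.0.  Zooma's categorical confidence labels are mapped monotonically:
HIGH=1.0, GOOD=0.75, MEDIUM=0.5, LOW=0.25.

Transient HTTP failures are retried up to 3 attempts with exponential
backoff; a source that still fails is recorded per-source (so a batch run
continues) rather than aborting the whole mapping job.
"""

from __future__ import annotations

import json
import logging
import os
import time
import urllib.error
import urllib.parse
import urllib.request
from typing import Callable, Dict, List, Optional, Sequence

from .mappers import MapperConfig, RawMatch, normalize

log = logging.getLogger(__name__)

BIOPORTAL_ANNOTATOR_URL = "https://data.bioontology.org/annotator"
ZOOMA_ANNOTATE_URL = "https://www.ebi.ac.uk/spot/zooma/v2/api/services/annotate"
BIOPORTAL_API_KEY_ENV = "BIOPORTAL_API_KEY"

ZOOMA_CONFIDENCE_SCORES = {"HIGH": 1.0, "GOOD": 0.75, "MEDIUM": 0.5, "LOW": 0.25}

MAX_ATTEMPTS = 3
BACKOFF_BASE_SECONDS = 1.0

Transport = Callable[[str], object]


class WebAPIError(Exception):
    """An HTTP request to an annotator service failed."""

    def __init__(self, message: str, status: Optional[int] = None):
        super().__init__(message)
        self.status = status


class MissingAPIKeyError(Exception):
    """No BioPortal API key supplied via argument or environment."""


def _default_transport(url: str) -> object:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:
            return json.load(resp)
    except urllib.error.HTTPError as e:
        raise WebAPIError(f"HTTP {e.code} from {url}", status=e.code) from e
    except urllib.error.URLError as e:
        raise WebAPIError(f"request to {url} failed: {e.reason}") from e


def _fetch_with_retry(
    url: str,
    transport: Transport,
    sleep: Callable[[float], None],
) -> object:
    last: Optional[Exception] = None
    for attempt in range(MAX_ATTEMPTS):
        try:
            return transport(url)
        except WebAPIError as e:
            last = e
            if attempt + 1 < MAX_ATTEMPTS:
                delay = BACKOFF_BASE_SECONDS * (2**attempt)
                log.warning("retrying after %s (attempt %d): %s", delay, attempt + 1, e)
                sleep(delay)
    assert last is not None
    raise last


def bioportal_map(
    sources: Sequence[str],
    ontology_acronym: str,
    config: Optional[MapperConfig] = None,
    api_key: Optional[str] = None,
    transport: Transport = _default_transport,
    sleep: Callable[[float], None] = time.sleep,
    failures: Optional[Dict[int, str]] = None,
) -> List[RawMatch]:
    """Annotate source strings with the BioPortal Annotator.

    Every returned annotation becomes a match with score 1.0 (the service
    reports no confidence).  ``failures`` — when given — collects
    ``source_index -> reason`` for sources whose request failed after all
    retries; such sources are simply absent from the result.
    """
    config = config or MapperConfig(mapper="bioportal")
    key = api_key or os.environ.get(BIOPORTAL_API_KEY_ENV)
    if not key:
        raise MissingAPIKeyError(
            f"BioPortal API key required: pass api_key or set {BIOPORTAL_API_KEY_ENV}"
        )
    results: List[RawMatch] = []
    for qi, source in enumerate(sources):
        params = urllib.parse.urlencode(
            {
                "text": normalize(source),
                "ontologies": ontology_acronym,
                "longest_only": "true",
                "apikey": key,
            }
        )
        url = f"{BIOPORTAL_ANNOTATOR_URL}?{params}"
        try:
            payload = _fetch_with_retry(url, transport, sleep)
        except WebAPIError as e:
            if failures is not None:
                failures[qi] = str(e)
            log.error("bioportal request for source %d failed: %s", qi, e)
            continue
        seen = set()
        for ann in payload or []:
            cls = ann.get("annotatedClass", {})
            iri = cls.get("@id")
            if not iri or iri in seen:
                continue
            seen.add(iri)
            results.append(
                RawMatch(
                    source_index=qi,
                    term_iri=iri,
                    matched_name=cls.get("prefLabel") or "",
                    name_kind="label",
                    score=1.0,
                )
            )
    return _truncate_per_source(results, config)


def zooma_map(
    sources: Sequence[str],
    ontology_name: str,
    config: Optional[MapperConfig] = None,
    transport: Transport = _default_transport,
    sleep: Callable[[float], None] = time.sleep,
    failures: Optional[Dict[int, str]] = None,
) -> List[RawMatch]:
    """Annotate source strings with Zooma against an OLS ontology.

    Zooma confidence labels are mapped to numeric scores via
    :data:`ZOOMA_CONFIDENCE_SCORES`; unknown labels score as LOW.
    """
    config = config or MapperConfig(mapper="zooma")
    results: List[RawMatch] = []
    for qi, source in enumerate(sources):
        params = urllib.parse.urlencode(
            {
                "propertyValue": normalize(source),
                "filter": f"required:[none],ontologies:[{ontology_name}]",
            }
        )
        url = f"{ZOOMA_ANNOTATE_URL}?{params}"
        try:
            payload = _fetch_with_retry(url, transport, sleep)
        except WebAPIError as e:
            if failures is not None:
                failures[qi] = str(e)
            log.error("zooma request for source %d failed: %s", qi, e)
            continue
        for ann in payload or []:
            confidence = str(ann.get("confidence", "LOW")).upper()
            score = ZOOMA_CONFIDENCE_SCORES.get(confidence, ZOOMA_CONFIDENCE_SCORES["LOW"])
            prop = ann.get("annotatedProperty") or {}
            for iri in ann.get("semanticTags", []):
                results.append(
                    RawMatch(
                        source_index=qi,
                        term_iri=iri,
                        matched_name=prop.get("propertyValue") or "",
                        name_kind="label",
                        score=score,
                    )
                )
    return _truncate_per_source(results, config)


def _truncate_per_source(matches: List[RawMatch], config: MapperConfig) -> List[RawMatch]:
    """Apply the shared ranking contract to web results."""
    by_source: Dict[int, List[RawMatch]] = {}
    for m in matches:
        by_source.setdefault(m.source_index, []).append(m)
    out: List[RawMatch] = []
    for qi in sorted(by_source):
        ranked = sorted(by_source[qi], key=lambda m: (-m.score, m.term_iri))
        out.extend(m for m in ranked[: config.max_mappings] if m.score >= config.min_score)
    return out
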