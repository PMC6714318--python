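"""The uniform extractor contract over heterogeneous NER backends.

Every backend — a deterministic mock used throughout the test suite, or a
REST adapter to a cloud NLP service — is driven through the same
:func:`extract` entry point and produces :class:`ExtractedTerm` mentions.
A failing backend raises :class:`~clinex.errors.BackendError` carrying its
id; the ensemble runner logs and continues with the remaining extractors.

Mock extractors match their fixture surfaces case-insensitively on word
boundaries, longest surface first, tolerating a simple plural ("hematoma"
matches "hematomas"). REST adapters are contract-only: request building and
response parsing are pure functions exercised against recorded payloads,
and credentials come from configuration, never from command-line flags.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .corpus import CATEGORIES, CATEGORY_OTHER, Document
from .errors import BackendError, ConfigurationError, ParseError, ValidationError


@dataclass(frozen=True)
class ExtractedTerm:
    """A surface mention produced by one extractor.

    ``span`` is a 0-based half-open [start, end) character offset into the
    raw document text, or ``None`` when the backend reports no offsets.
    """

    surface: str
    span: tuple[int, int] | None
    category: str
    extractor_id: str
    negated: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValidationError("ExtractedTerm.surface must be non-empty")
        if self.category not in CATEGORIES:
            object.__setattr__(self, "category", CATEGORY_OTHER)

    def with_negated(self, negated: bool) -> "ExtractedTerm":
        return replace(self, negated=negated)

    def to_dict(self) -> dict:
        return {
            "surface": self.surface,
            "span": list(self.span) if self.span else None,
            "category": self.category,
            "extractor_id": self.extractor_id,
            "negated": self.negated,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ExtractedTerm":
        span = d.get("span")
        return cls(
            surface=d["surface"],
            span=tuple(span) if span else None,
            category=d["category"],
            extractor_id=d["extractor_id"],
            negated=bool(d.get("negated", False)),
        )


@dataclass(frozen=True)
class ExtractorSpec:
    """Configuration for one backend.

    ``kind`` is ``mock`` (fixture-driven, pure) or ``rest``. Mock fixtures
    map surface form -> category; REST specs carry an endpoint, a bearer
    token and a type-mapping table from backend entity labels to our
    categories (unknown labels fall back to ``other``).
    """

    extractor_id: str
    kind: str = "mock"
    supported_categories: frozenset[str] = frozenset(CATEGORIES)
    fixture: Mapping[str, str] = field(default_factory=dict)
    endpoint: str | None = None
    token: str | None = None
    type_mapping: Mapping[str, str] = field(default_factory=dict)
    # diagnostic hook: when set, extract() raises BackendError with this
    # message, letting callers exercise the degraded-ensemble path offline
    fail_message: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mock", "rest"):
            raise ConfigurationError(f"unknown extractor kind {self.kind!r}")


def _sort_terms(terms: list[ExtractedTerm]) -> list[ExtractedTerm]:
    return sorted(terms, key=lambda t: (t.span[0] if t.span else 1 << 30, t.surface))


def _extract_mock(document: Document, spec: ExtractorSpec) -> list[ExtractedTerm]:
    claimed: list[tuple[int, int]] = []
    terms: list[ExtractedTerm] = []
    # longest surface first so "orthostatic hypotension" beats "hypotension"
    for surface in sorted(spec.fixture, key=lambda s: (-len(s), s)):
        category = spec.fixture[surface]
        if category not in spec.supported_categories:
            continue
        pattern = re.compile(rf"\b{re.escape(surface)}s?\b", re.IGNORECASE)
        for m in pattern.finditer(document.text):
            if any(m.start() < e and s < m.end() for s, e in claimed):
                continue
            claimed.append((m.start(), m.end()))
            terms.append(
                ExtractedTerm(
                    surface=document.text[m.start() : m.end()],
                    span=(m.start(), m.end()),
                    category=category,
                    extractor_id=spec.extractor_id,
                )
            )
    return _sort_terms(terms)


def build_rest_request(document: Document, spec: ExtractorSpec) -> dict:
    """Build a serializable request description; no network side effect.

    The body asks the backend for entity mentions only, via the standard
    ``{"features": "entities"}`` parameter.
    """
    if spec.kind != "rest":
        raise ConfigurationError(f"{spec.extractor_id}: not a REST extractor")
    if not spec.token:
        raise ConfigurationError(f"{spec.extractor_id}: missing API token")
    if not spec.endpoint:
        raise ConfigurationError(f"{spec.extractor_id}: missing endpoint")
    return {
        "url": spec.endpoint,
        "method": "POST",
        "headers": {
            "Authorization": f"Bearer {spec.token}",
            "Content-Type": "application/json",
        },
        "body": {"text": document.text, "features": "entities"},
    }


def parse_rest_response(payload: str, spec: ExtractorSpec) -> list[ExtractedTerm]:
    """Map a backend JSON payload onto ExtractedTerms.

    Accepts either a bare entity array or ``{"entities": [...]}``; each
    entity carries ``text`` (or ``surface``), an optional ``type`` resolved
    through ``spec.type_mapping``, and optional ``start``/``end`` offsets.
    """
    try:
        data = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise ParseError(spec.extractor_id, f"malformed JSON response: {exc}") from exc
    entities = data.get("entities", []) if isinstance(data, Mapping) else data
    terms: list[ExtractedTerm] = []
    for ent in entities:
        surface = ent.get("text") or ent.get("surface")
        if not surface:
            continue
        category = spec.type_mapping.get(str(ent.get("type")), CATEGORY_OTHER)
        if category not in spec.supported_categories:
            continue
        span = None
        if "start" in ent and "end" in ent:
            span = (int(ent["start"]), int(ent["end"]))
        terms.append(
            ExtractedTerm(
                surface=str(surface),
                span=span,
                category=category,
                extractor_id=spec.extractor_id,
            )
        )
    return _sort_terms(terms)


def _extract_rest(document: Document, spec: ExtractorSpec) -> list[ExtractedTerm]:
    import urllib.error
    import urllib.request

    request = build_rest_request(document, spec)
    req = urllib.request.Request(
        request["url"],
        data=json.dumps(request["body"]).encode("utf-8"),
        headers=request["headers"],
        method=request["method"],
    )
    try:
        with urllib.request.urlopen(req, timeout=30) as resp:
            payload = resp.read().decode("utf-8")
    except (urllib.error.URLError, OSError) as exc:
        raise BackendError(spec.extractor_id, f"transport failure: {exc}") from exc
    return parse_rest_response(payload, spec)


def extract(document: Document, spec: ExtractorSpec) -> list[ExtractedTerm]:
    """Run one extractor on one document.

    Output is deterministic (sorted by span start, then surface) and every
    term carries ``spec.extractor_id``. Backend failures surface as
    :class:`BackendError` so the caller can degrade gracefully.
    """
    if spec.fail_message is not None:
        raise BackendError(spec.extractor_id, spec.fail_message)
    if not document.text:
        return []
    if spec.kind == "mock":
        return _extract_mock(document, spec)
    return _extract_rest(document, spec)


def run_ensemble(
    documents: Sequence[Document], specs: Sequence[ExtractorSpec]
) -> tuple[dict[str, dict[str, list[ExtractedTerm]]], list[str]]:
    """Run every extractor over every document, skipping failed backends.

    Returns ``(outputs, failed_ids)`` where outputs maps extractor_id ->
    doc_id -> terms. An extractor that fails on any document is dropped
    entirely and reported in ``failed_ids``; the ensemble never raises on a
    single backend failure.
    """
    import logging

    log = logging.getLogger(__name__)
    outputs: dict[str, dict[str, list[ExtractedTerm]]] = {}
    failed: list[str] = []
    for spec in specs:
        per_doc: dict[str, list[ExtractedTerm]] = {}
        try:
            for doc in documents:
                per_doc[doc.doc_id] = extract(doc, spec)
        except BackendError as exc:
            log.warning("extractor %s failed, continuing without it: %s", spec.extractor_id, exc)
            failed.append(spec.extractor_id)
            continue
        outputs[spec.extractor_id] = per_doc
    return outputs, failed
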