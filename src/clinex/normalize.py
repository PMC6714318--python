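"""Concept normalization: surface forms to ranked standardized codes.

A metathesaurus lookup (UMLS-style) returns, for each extracted term, its
top matched codes ranked by similarity — at most ten, best first. The
downstream ensemble compares terms by these ranked code lists, so the
lookup interface matters more than the backing store: here it is a local
:class:`ConceptLexicon` (a JSON file mapping surface strings to ordered
code lists) with the same contract a live terminology service would honour.

Lookup normalization: lowercase, strip punctuation, collapse whitespace,
and fall back to stripping a trailing "s" when there is no exact hit, so
"hematomas" resolves to the "hematoma" entry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import ValidationError
from .extractors import ExtractedTerm

MAX_MATCHES = 10
TOP_RANKS = 3


def normalize_surface(surface: str) -> str:
    """Canonical lookup key: lowercase, punctuation stripped, single spaces."""
    s = re.sub(r"[^\w\s]", " ", surface.lower())
    return re.sub(r"\s+", " ", s).strip()


@dataclass(frozen=True)
class ConceptMatch:
    """One ranked code candidate for a term."""

    code_system: str
    code: str
    rank: int
    score: float = 1.0

    def __post_init__(self) -> None:
        # rank may exceed MAX_MATCHES on a raw candidate list; match lists
        # are truncated to MAX_MATCHES wherever they are assembled
        if self.rank < 1:
            raise ValidationError(f"rank {self.rank} must be >= 1")
        if not 0.0 <= self.score <= 1.0:
            raise ValidationError(f"score {self.score} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str]:
        """Identity used for term comparison: (code_system, code)."""
        return (self.code_system, self.code)


def _validate_matches(matches: Sequence[ConceptMatch]) -> tuple[ConceptMatch, ...]:
    matches = tuple(matches)[:MAX_MATCHES]
    if [m.rank for m in matches] != list(range(1, len(matches) + 1)):
        raise ValidationError("match ranks must be contiguous from 1, ascending")
    return matches


@dataclass(frozen=True)
class NormalizedTerm:
    """An extracted term plus its ranked code matches (possibly empty)."""

    term: ExtractedTerm
    matches: tuple[ConceptMatch, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "matches", _validate_matches(self.matches))

    @property
    def primary_code(self) -> tuple[str, str] | None:
        """The top-ranked (code_system, code), or None when unmatched."""
        return self.matches[0].key if self.matches else None

    @property
    def normalized_surface(self) -> str:
        return normalize_surface(self.term.surface)

    @property
    def dedup_key(self) -> tuple:
        """Primary code when matched, else the normalized surface."""
        if self.primary_code is not None:
            return ("code",) + self.primary_code
        return ("surface", self.normalized_surface)

    def to_dict(self) -> dict:
        return {
            "term": self.term.to_dict(),
            "matches": [
                {"code_system": m.code_system, "code": m.code,
                 "rank": m.rank, "score": m.score}
                for m in self.matches
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizedTerm":
        return cls(
            term=ExtractedTerm.from_dict(d["term"]),
            matches=tuple(ConceptMatch(**m) for m in d["matches"]),
        )


@dataclass
class ConceptLexicon:
    """Local surface -> ranked code list mapping; one code system per lexicon.

    ``categories`` optionally records each surface's clinical category
    (used by the synthetic generator and mock fixtures); it plays no role
    in lookup.
    """

    code_system: str = "CUI"
    entries: dict[str, tuple[ConceptMatch, ...]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = {
            normalize_surface(k): _validate_matches(v) for k, v in self.entries.items()
        }
        self.categories = {normalize_surface(k): v for k, v in self.categories.items()}

    def lookup(self, surface: str) -> tuple[ConceptMatch, ...]:
        key = normalize_surface(surface)
        hit = self.entries.get(key)
        if hit is None and key.endswith("s"):
            hit = self.entries.get(key[:-1])
        return hit or ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "code_system": self.code_system,
            "entries": {
                k: [{"code_system": m.code_system, "code": m.code,
                     "rank": m.rank, "score": m.score} for m in v]
                for k, v in self.entries.items()
            },
            "categories": self.categories,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "ConceptLexicon":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            code_system=payload.get("code_system", "CUI"),
            entries={
                k: tuple(ConceptMatch(**m) for m in v)
                for k, v in payload["entries"].items()
            },
            categories=payload.get("categories", {}),
        )


def encode_term(term: ExtractedTerm, lexicon: ConceptLexicon) -> NormalizedTerm:
    """Look a term up in the lexicon; an unknown surface yields empty matches
    (an unmatchable entity, not an error)."""
    return NormalizedTerm(term=term, matches=lexicon.lookup(term.surface))


def deduplicate_entities(terms: Sequence[NormalizedTerm]) -> list[NormalizedTerm]:
    """Collapse terms of one document sharing a primary code (or, unmatched,
    a normalized surface) to a single representative — the earliest mention
    by span start. Idempotent; output ordered by first occurrence."""
    groups: dict[tuple, list[tuple[tuple, int, NormalizedTerm]]] = {}
    order: list[tuple] = []
    for idx, t in enumerate(terms):
        key = t.dedup_key
        start = t.term.span[0] if t.term.span else 1 << 30
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(((start, idx), idx, t))
    return [min(groups[k])[2] for k in order]
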