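"""Rule-based negation detection in the NegEx style.

Clinical narratives are dense with negated findings ("no fracture",
"patient denies a headache"); an extractor that reports every mention will
count negated concepts as present. This module detects negation scopes with
trigger phrases and a bounded token window inside each sentence, flags
extracted terms whose spans fall inside a scope, and optionally filters them
out (the pipeline's kappa switch).

Algorithm, per sentence:

1. tokenize on whitespace; a token matches a trigger word after lowercasing
   and stripping surrounding punctuation;
2. scan left to right, longest trigger phrase first, checking pseudo-triggers
   before real ones (a matched pseudo-trigger consumes its tokens and
   produces no scope);
3. a PRE trigger opens a forward scope of at most ``window`` tokens, cut
   short by a terminator phrase or the sentence end; a POST trigger opens
   the symmetric backward scope;
4. overlapping scopes within a sentence are merged.

Sentence boundaries are ``. ! ? ;`` followed by whitespace — deliberately
simple so the core has no tokenizer dependency.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ValidationError
from .extractors import ExtractedTerm

_DEFAULT_WINDOW = 5

_ROLE_FIELDS = {"PRE": "pre_triggers", "POST": "post_triggers",
                "PSEUDO": "pseudo_triggers", "TERM": "terminators"}


@dataclass
class NegationLexicon:
    """Trigger phrase lists plus the scope window (in tokens)."""

    pre_triggers: list[str] = field(default_factory=list)
    post_triggers: list[str] = field(default_factory=list)
    pseudo_triggers: list[str] = field(default_factory=list)
    terminators: list[str] = field(default_factory=list)
    window: int = _DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValidationError("negation window must be > 0")
        for name in _ROLE_FIELDS.values():
            phrases = [p.strip().lower() for p in getattr(self, name)]
            if any(not p for p in phrases):
                raise ValidationError(f"empty phrase in {name}")
            setattr(self, name, phrases)


@dataclass(frozen=True)
class NegationSpan:
    """A negated character region and the trigger that opened it."""

    start: int
    end: int
    trigger: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError("NegationSpan requires start < end")

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def load_negation_lexicon(path: str | Path | None = None,
                          window: int = _DEFAULT_WINDOW) -> NegationLexicon:
    """Load a trigger lexicon from a ``phrase<TAB>role`` file; with no path,
    load the packaged default list."""
    if path is None:
        source = resources.files("clinex.data").joinpath("negex_triggers.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    lex = NegationLexicon(window=window)
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        phrase, _, role = line.partition("\t")
        role = role.strip().upper()
        if role not in _ROLE_FIELDS:
            raise ValidationError(f"line {lineno}: unknown trigger role {role!r}")
        getattr(lex, _ROLE_FIELDS[role]).append(phrase.strip().lower())
    return NegationLexicon(
        pre_triggers=lex.pre_triggers,
        post_triggers=lex.post_triggers,
        pseudo_triggers=lex.pseudo_triggers,
        terminators=lex.terminators,
        window=window,
    )


def _sentences(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences: split at [.!?;] followed by whitespace."""
    spans = []
    start = 0
    for m in re.finditer(r"[.!?;](?=\s)", text):
        spans.append((start, m.end()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return [(s, e) for s, e in spans if text[s:e].strip()]


def _tokens(text: str, start: int, end: int) -> list[tuple[int, int, str]]:
    """(char_start, char_end, normalized) for each whitespace token."""
    out = []
    for m in re.finditer(r"\S+", text[start:end]):
        norm = m.group().lower().strip(string.punctuation)
        out.append((start + m.start(), start + m.end(), norm))
    return out


def _match_phrase(tokens: Sequence[tuple[int, int, str]], idx: int,
                  phrases: Sequence[tuple[str, ...]]) -> int:
    """Length (in tokens) of the longest phrase matching at ``idx``, or 0."""
    for words in phrases:
        n = len(words)
        if idx + n <= len(tokens) and all(
            tokens[idx + k][2] == words[k] for k in range(n)
        ):
            return n
    return 0


def detect_negation_spans(text: str, lexicon: NegationLexicon) -> list[NegationSpan]:
    """Find negated character regions; merged per sentence, sorted by start."""
    if not text.strip():
        return []

    def split(phrases: Iterable[str]) -> list[tuple[str, ...]]:
        return sorted((tuple(p.split()) for p in phrases), key=len, reverse=True)

    pseudo = split(lexicon.pseudo_triggers)
    pre = split(lexicon.pre_triggers)
    post = split(lexicon.post_triggers)
    term = split(lexicon.terminators)

    raw: list[NegationSpan] = []
    for s_start, s_end in _sentences(text):
        tokens = _tokens(text, s_start, s_end)
        i = 0
        while i < len(tokens):
            n = _match_phrase(tokens, i, pseudo)
            if n:
                i += n
                continue
            n = _match_phrase(tokens, i, pre)
            if n:
                trigger = " ".join(tokens[i + k][2] for k in range(n))
                j = i + n
                scope_end = j
                while scope_end < min(j + lexicon.window, len(tokens)):
                    if _match_phrase(tokens, scope_end, term):
                        break
                    scope_end += 1
                if scope_end > j:
                    raw.append(NegationSpan(tokens[j][0], tokens[scope_end - 1][1], trigger))
                i += n
                continue
            n = _match_phrase(tokens, i, post)
            if n:
                trigger = " ".join(tokens[i + k][2] for k in range(n))
                scope_start = i
                lo = max(i - lexicon.window, 0)
                while scope_start > lo:
                    if _match_phrase(tokens, scope_start - 1, term):
                        break
                    scope_start -= 1
                if scope_start < i:
                    raw.append(NegationSpan(tokens[scope_start][0], tokens[i - 1][1], trigger))
                i += n
                continue
            i += 1

    raw.sort(key=lambda s: (s.start, s.end))
    merged: list[NegationSpan] = []
    for span in raw:
        if merged and span.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = NegationSpan(prev.start, max(prev.end, span.end), prev.trigger)
        else:
            merged.append(span)
    return merged


def flag_negated(terms: Sequence[ExtractedTerm], spans: Sequence[NegationSpan],
                 text: str = "") -> list[ExtractedTerm]:
    """Set ``negated=True`` on terms overlapping any negation span.

    Terms without character spans are located by the first case-insensitive
    occurrence of their surface in ``text``; input order is preserved and
    any character overlap flags the term.
    """
    out: list[ExtractedTerm] = []
    for t in terms:
        span = t.span
        if span is None and text:
            pos = text.lower().find(t.surface.lower())
            if pos >= 0:
                span = (pos, pos + len(t.surface))
        negated = span is not None and any(s.overlaps(*span) for s in spans)
        out.append(t.with_negated(negated) if negated != t.negated else t)
    return out


def apply_negation_filter(terms: Sequence[ExtractedTerm], kappa: bool) -> list[ExtractedTerm]:
    """kappa=True drops negated terms; kappa=False returns the input unchanged."""
    if not kappa:
        return list(terms)
    return [t for t in terms if not t.negated]
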