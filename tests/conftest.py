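"""Shared builders for the test suite."""

from __future__ import annotations

import pytest

from clinex import ConceptLexicon, ConceptMatch, ExtractedTerm, NormalizedTerm


def make_term(
    surface: str = "asthma",
    span: tuple[int, int] | None = (0, 6),
    category: str = "medical_condition",
    extractor_id: str = "ex1",
    negated: bool = False,
) -> ExtractedTerm:
    return ExtractedTerm(
        surface=surface, span=span, category=category,
        extractor_id=extractor_id, negated=negated,
    )


def make_matches(codes: list[str], code_system: str = "CUI") -> tuple[ConceptMatch, ...]:
    return tuple(
        ConceptMatch(code_system=code_system, code=c, rank=i + 1,
                     score=round(1.0 - 0.05 * i, 3))
        for i, c in enumerate(codes)
    )


def make_norm(
    codes: list[str],
    surface: str = "asthma",
    extractor_id: str = "ex1",
    span: tuple[int, int] | None = (0, 6),
) -> NormalizedTerm:
    return NormalizedTerm(
        term=make_term(surface=surface, span=span, extractor_id=extractor_id),
        matches=make_matches(codes),
    )


@pytest.fixture
def tiny_lexicon() -> ConceptLexicon:
    return ConceptLexicon(
        code_system="CUI",
        entries={
            "asthma": make_matches(["C0004096", "C0264408", "C0155877"]),
            "hematoma": make_matches(["C0018944", "C0852397"]),
            "orthostatic hypotension": make_matches(["C0020651"]),
            "depression": make_matches(["C0011570", "C0011581"]),
        },
        categories={
            "asthma": "medical_condition",
            "hematoma": "medical_condition",
            "orthostatic hypotension": "medical_condition",
            "depression": "medical_condition",
        },
    )
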