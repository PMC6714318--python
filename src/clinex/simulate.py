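"""Synthetic corpora, lexica and extractor outputs for offline testing.

Real clinical corpora with gold annotations are access-restricted, and the
cloud NER backends need accounts. This module generates the whole offline
world instead: a concept lexicon with ranked codes (including near-synonym
surface pairs that share top-ranked codes, so the similarity-based merging
is actually exercised), template-prose documents with embedded gold
entities (a configurable fraction wrapped in negation triggers and marked
``absent``), and per-extractor term lists with controlled sensitivity and
spurious-mention rates.

Every generator is a pure function of (spec, seed): identical seeds give
identical output. The default profile — 50 documents, three extractors
with sensitivities 0.9 / 0.8 / 0.7 and 0.5 spurious mentions per document,
15 % of gold entities negated — is the study condition used throughout the
test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import (
    CATEGORY_CONDITION,
    CATEGORY_DRUG,
    POLARITY_ABSENT,
    POLARITY_PRESENT,
    Document,
    GoldAnnotation,
)
from .errors import ValidationError
from .extractors import ExtractedTerm
from .normalize import MAX_MATCHES, ConceptLexicon, ConceptMatch, normalize_surface

# fixed clinical stubs so worked examples use recognizable concepts
_CLINICAL_STUBS: tuple[tuple[str, str], ...] = (
    ("asthma", CATEGORY_CONDITION),
    ("depression", CATEGORY_CONDITION),
    ("hematoma", CATEGORY_CONDITION),
    ("orthostatic hypotension", CATEGORY_CONDITION),
    ("obesity", CATEGORY_CONDITION),
    ("hypertension", CATEGORY_CONDITION),
    ("gastroesophageal reflux", CATEGORY_CONDITION),
    ("fracture", CATEGORY_CONDITION),
    ("headache", CATEGORY_CONDITION),
    ("pneumonia", CATEGORY_CONDITION),
    ("aspirin", CATEGORY_DRUG),
    ("metformin", CATEGORY_DRUG),
    ("lisinopril", CATEGORY_DRUG),
    ("warfarin", CATEGORY_DRUG),
    ("simvastatin", CATEGORY_DRUG),
)

_PRESENT_TEMPLATES = (
    "history of {e} was noted",
    "the patient was treated for {e}",
    "{e} present on admission",
    "examination confirmed {e}",
)
_NEGATED_TEMPLATES = (
    "no {e} was found",
    "patient denies {e}",
    "without {e} on examination",
)
_FILLER = (
    "vital signs were stable",
    "the patient was seen on the ward",
    "follow up was arranged with the general practitioner",
)

_SYLLABLES = ("ba", "co", "di", "fe", "ga", "hi", "lo", "mu", "ne", "pa",
              "ru", "sa", "ti", "vo", "xe", "zy")


@dataclass(frozen=True)
class ExtractorProfile:
    """Simulated behaviour of one backend."""

    extractor_id: str
    sensitivity: float  # probability of emitting each true entity mention
    spurious_rate: float  # expected spurious mentions per document
    category_support: frozenset[str] = frozenset({CATEGORY_CONDITION, CATEGORY_DRUG})

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValidationError("sensitivity must lie in [0, 1]")
        if self.spurious_rate < 0.0:
            raise ValidationError("spurious_rate must be >= 0")


def default_profiles() -> list[ExtractorProfile]:
    return [
        ExtractorProfile("alpha_ner", sensitivity=0.9, spurious_rate=0.5),
        ExtractorProfile("beta_ner", sensitivity=0.8, spurious_rate=0.5),
        ExtractorProfile("gamma_ner", sensitivity=0.7, spurious_rate=0.5),
    ]


@dataclass
class SimulationSpec:
    """Study conditions for one synthetic world."""

    seed: int = 0
    n_docs: int = 50
    lexicon_size: int = 40
    entities_per_doc: tuple[int, int] = (2, 5)
    negation_rate: float = 0.15
    extractor_profiles: list[ExtractorProfile] = field(default_factory=default_profiles)

    def __post_init__(self) -> None:
        if isinstance(self.entities_per_doc, int):
            self.entities_per_doc = (self.entities_per_doc, self.entities_per_doc)
        lo, hi = self.entities_per_doc
        if self.n_docs < 0 or self.lexicon_size < 1 or lo < 1 or hi < lo:
            raise ValidationError("invalid simulation sizes")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ValidationError("negation_rate must lie in [0, 1]")


def _rng(spec: SimulationSpec, stage: int) -> np.random.Generator:
    # independent stream per stage so regenerating one artifact never
    # perturbs another
    return np.random.default_rng([spec.seed, stage])


def _pseudo_term(rng: np.random.Generator) -> str:
    n = int(rng.integers(3, 5))
    return "".join(rng.choice(_SYLLABLES) for _ in range(n))


def generate_lexicon(spec: SimulationSpec) -> ConceptLexicon:
    """A concept lexicon of ``lexicon_size`` surfaces.

    Starts with a fixed clinical stub list, then pronounceable pseudo-terms;
    every fourth entry spawns a near-synonym (``<surface> disorder``)
    sharing its two top-ranked codes, guaranteeing pairs with similarity
    weight >= 0.25 for the merge logic to chew on.
    """
    rng = _rng(spec, stage=1)
    counter = 0

    def next_code() -> str:
        nonlocal counter
        counter += 1
        return f"C{counter:07d}"

    def make_matches(shared: tuple[str, ...] = ()) -> tuple[ConceptMatch, ...]:
        n = int(rng.integers(max(3, len(shared)), MAX_MATCHES + 1))
        codes = list(shared) + [next_code() for _ in range(n - len(shared))]
        return tuple(
            ConceptMatch(code_system="CUI", code=c, rank=i + 1,
                         score=round(max(0.05, 0.97 - 0.08 * i), 3))
            for i, c in enumerate(codes)
        )

    entries: dict[str, tuple[ConceptMatch, ...]] = {}
    categories: dict[str, str] = {}

    def add(surface: str, category: str, matches: tuple[ConceptMatch, ...]) -> None:
        entries[surface] = matches
        categories[surface] = category

    base = 0
    while len(entries) < spec.lexicon_size:
        if base < len(_CLINICAL_STUBS):
            surface, category = _CLINICAL_STUBS[base]
        else:
            surface = _pseudo_term(rng)
            if surface in entries:
                continue
            category = CATEGORY_CONDITION if base % 2 == 0 else CATEGORY_DRUG
        matches = make_matches()
        add(surface, category, matches)
        base += 1
        if base % 4 == 0 and len(entries) < spec.lexicon_size:
            synonym = f"{surface} disorder"
            add(synonym, category, make_matches(shared=tuple(m.code for m in matches[:2])))
    return ConceptLexicon(code_system="CUI", entries=entries, categories=categories)


def generate_corpus(
    spec: SimulationSpec, lexicon: ConceptLexicon
) -> tuple[list[Document], list[GoldAnnotation]]:
    """Template-prose documents with embedded gold entities.

    A ``negation_rate`` fraction of entities are wrapped in negation-trigger
    templates and annotated ``absent``; the rest are asserted and annotated
    ``present``. Entity counts follow ``entities_per_doc`` exactly.
    """
    rng = _rng(spec, stage=2)
    surfaces = sorted(lexicon.entries)
    lo, hi = spec.entities_per_doc
    documents: list[Document] = []
    gold: list[GoldAnnotation] = []
    for i in range(spec.n_docs):
        doc_id = f"doc{i:04d}"
        n_entities = int(rng.integers(lo, hi + 1))
        # sample distinct CONCEPTS: never both a surface and its generated
        # near-synonym ("<surface> disorder") in one document
        chosen: list[str] = []
        for k in rng.permutation(len(surfaces)):
            if len(chosen) == min(n_entities, len(surfaces)):
                break
            surface = surfaces[int(k)]
            base = surface.removesuffix(" disorder")
            if any(c == f"{surface} disorder" or base == c.removesuffix(" disorder")
                   for c in chosen):
                continue
            chosen.append(surface)
        sentences = [str(rng.choice(_FILLER))]
        for surface in chosen:
            negate = bool(rng.random() < spec.negation_rate)
            pool = _NEGATED_TEMPLATES if negate else _PRESENT_TEMPLATES
            sentences.append(str(rng.choice(pool)).format(e=surface))
            matches = lexicon.entries[surface]
            gold.append(
                GoldAnnotation(
                    doc_id=doc_id,
                    surface=surface,
                    codes=(matches[0].key,) if matches else (),
                    category=lexicon.categories.get(surface, CATEGORY_CONDITION),
                    polarity=POLARITY_ABSENT if negate else POLARITY_PRESENT,
                )
            )
        documents.append(Document(doc_id=doc_id, text=". ".join(sentences) + "."))
    return documents, gold


def simulate_extractor_outputs(
    documents: list[Document],
    gold: list[GoldAnnotation],
    spec: SimulationSpec,
) -> dict[str, dict[str, list[ExtractedTerm]]]:
    """Per-extractor, per-document mention lists.

    Each profile emits each gold mention of a supported category with
    probability ``sensitivity`` (with its true character span), and adds
    Poisson(``spurious_rate``) spurious lexicon terms per document (span
    unknown). Deterministic under the spec seed.
    """
    if not spec.extractor_profiles:
        raise ValidationError("at least one extractor profile required")
    rng = _rng(spec, stage=3)
    lexicon = generate_lexicon(spec)
    surfaces = sorted(lexicon.entries)
    gold_by_doc: dict[str, list[GoldAnnotation]] = {}
    for ann in gold:
        gold_by_doc.setdefault(ann.doc_id, []).append(ann)

    outputs: dict[str, dict[str, list[ExtractedTerm]]] = {}
    for profile in spec.extractor_profiles:
        per_doc: dict[str, list[ExtractedTerm]] = {}
        for doc in documents:
            terms: list[ExtractedTerm] = []
            doc_surfaces = {normalize_surface(a.surface or "") for a in gold_by_doc.get(doc.doc_id, [])}
            for ann in gold_by_doc.get(doc.doc_id, []):
                if ann.category not in profile.category_support:
                    continue
                if rng.random() >= profile.sensitivity:
                    continue
                assert ann.surface is not None
                pos = doc.text.lower().find(ann.surface.lower())
                span = (pos, pos + len(ann.surface)) if pos >= 0 else None
                terms.append(
                    ExtractedTerm(
                        surface=doc.text[span[0]:span[1]] if span else ann.surface,
                        span=span,
                        category=ann.category,
                        extractor_id=profile.extractor_id,
                    )
                )
            n_spurious = int(rng.poisson(profile.spurious_rate))
            for _ in range(n_spurious):
                surface = surfaces[int(rng.integers(len(surfaces)))]
                if normalize_surface(surface) in doc_surfaces:
                    continue  # would be a true mention, not a spurious one
                category = lexicon.categories.get(surface, CATEGORY_CONDITION)
                if category not in profile.category_support:
                    continue
                terms.append(
                    ExtractedTerm(
                        surface=surface,
                        span=None,
                        category=category,
                        extractor_id=profile.extractor_id,
                    )
                )
            per_doc[doc.doc_id] = terms
        outputs[profile.extractor_id] = per_doc
    return outputs


def generate_world(
    spec: SimulationSpec,
) -> tuple[ConceptLexicon, list[Document], list[GoldAnnotation],
           dict[str, dict[str, list[ExtractedTerm]]]]:
    """Convenience bundle: lexicon, corpus, gold and extractor outputs."""
    lexicon = generate_lexicon(spec)
    documents, gold = generate_corpus(spec, lexicon)
    outputs = simulate_extractor_outputs(documents, gold, spec)
    return lexicon, documents, gold, outputs
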