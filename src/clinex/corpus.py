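"""Documents, gold annotations and result files.

Clinical corpora are plain text: either a directory of ``*.txt`` files (one
document each, filename stem as id) or a JSONL file with ``doc_id``/``text``
records. Gold standards are JSONL or CSV; a gold row names a concept either
by surface form, by standardized codes, or both, and carries a present/absent
polarity so that classification-style gold (document-level condition labels)
and exhaustive mention-style gold can share one representation. All
interchange is UTF-8 JSON/JSONL.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InputError, ValidationError

CATEGORY_CONDITION = "medical_condition"
CATEGORY_DRUG = "pharmaceutical_drug"
CATEGORY_OTHER = "other"
CATEGORIES = (CATEGORY_CONDITION, CATEGORY_DRUG, CATEGORY_OTHER)

POLARITY_PRESENT = "present"
POLARITY_ABSENT = "absent"


@dataclass(frozen=True)
class Document:
    """One clinical text; the unit of extraction and evaluation."""

    doc_id: str
    text: str
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValidationError("Document requires a non-empty doc_id")


@dataclass(frozen=True)
class GoldAnnotation:
    """A gold-standard concept for one document.

    ``polarity`` is ``present`` for concepts asserted in the text and
    ``absent`` for concepts annotated as not applying (undecided/unknown
    labels are folded into ``absent``).
    """

    doc_id: str
    surface: str | None = None
    codes: tuple[tuple[str, str], ...] = ()
    category: str = CATEGORY_CONDITION
    polarity: str = POLARITY_PRESENT

    def __post_init__(self) -> None:
        if not self.surface and not self.codes:
            raise ValidationError(
                f"gold annotation for {self.doc_id!r} needs a surface or codes"
            )
        if self.polarity not in (POLARITY_PRESENT, POLARITY_ABSENT):
            object.__setattr__(self, "polarity", POLARITY_ABSENT)


@dataclass
class ExtractionResult:
    """Integrated output for one document: accepted and rejected entities."""

    doc_id: str
    accepted_entities: list  # list[MergedEntity]
    rejected_entities: list  # list[MergedEntity]
    config_used: "IntegrationConfig"  # noqa: F821 - defined in integrate


def _normalize_polarity(value: object) -> str:
    if isinstance(value, str) and value.strip().lower() == POLARITY_PRESENT:
        return POLARITY_PRESENT
    return POLARITY_ABSENT


def _parse_codes(value: object) -> tuple[tuple[str, str], ...]:
    """Accept ``[["CUI","C0004096"], ...]``, ``[{"code_system":...}]`` or the
    CSV encoding ``"CUI:C0004096|ICD10:J45"``."""
    if value in (None, "", []):
        return ()
    if isinstance(value, str):
        pairs = []
        for chunk in value.split("|"):
            system, _, code = chunk.partition(":")
            if not code:
                raise ValidationError(f"cannot parse code {chunk!r}")
            pairs.append((system.strip(), code.strip()))
        return tuple(pairs)
    out = []
    for item in value:  # type: ignore[union-attr]
        if isinstance(item, Mapping):
            out.append((str(item["code_system"]), str(item["code"])))
        else:
            system, code = item
            out.append((str(system), str(code)))
    return tuple(out)


def read_corpus(path: str | Path, fmt: str | None = None) -> list[Document]:
    """Read documents from a JSONL file or a directory of ``.txt`` files.

    Returns documents sorted lexicographically by ``doc_id``; duplicate ids
    raise :class:`ValidationError` naming the offending id.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"corpus path does not exist: {path}")
    if fmt is None:
        fmt = "text_dir" if path.is_dir() else "jsonl"

    docs: list[Document] = []
    if fmt == "text_dir":
        for txt in sorted(path.glob("*.txt")):
            docs.append(Document(doc_id=txt.stem, text=txt.read_text(encoding="utf-8")))
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                record = json.loads(line)
                docs.append(
                    Document(
                        doc_id=str(record["doc_id"]),
                        text=str(record["text"]),
                        metadata=record.get("metadata", {}),
                    )
                )
    else:
        raise InputError(f"unknown corpus format {fmt!r}")

    seen: set[str] = set()
    for doc in docs:
        if doc.doc_id in seen:
            raise ValidationError(f"duplicate doc_id {doc.doc_id!r} in corpus")
        seen.add(doc.doc_id)
    docs.sort(key=lambda d: d.doc_id)
    return docs


def write_corpus(documents: Iterable[Document], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(json.dumps({"doc_id": doc.doc_id, "text": doc.text}) + "\n")


def read_gold(path: str | Path) -> list[GoldAnnotation]:
    """Read gold annotations from JSONL or CSV.

    Any polarity outside {present, absent} is normalized to ``absent``; a
    record with neither surface nor codes raises :class:`ValidationError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"gold path does not exist: {path}")
    records: list[Mapping[str, object]]
    if path.suffix.lower() == ".csv":
        with path.open(encoding="utf-8", newline="") as fh:
            records = list(csv.DictReader(fh))
    else:
        with path.open(encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]

    gold: list[GoldAnnotation] = []
    for rec in records:
        gold.append(
            GoldAnnotation(
                doc_id=str(rec["doc_id"]),
                surface=(str(rec["surface"]) if rec.get("surface") else None),
                codes=_parse_codes(rec.get("codes")),
                category=str(rec.get("category") or CATEGORY_CONDITION),
                polarity=_normalize_polarity(rec.get("polarity", POLARITY_PRESENT)),
            )
        )
    return gold


def write_gold(gold: Iterable[GoldAnnotation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for ann in gold:
            fh.write(
                json.dumps(
                    {
                        "doc_id": ann.doc_id,
                        "surface": ann.surface,
                        "codes": [list(c) for c in ann.codes],
                        "category": ann.category,
                        "polarity": ann.polarity,
                    }
                )
                + "\n"
            )


def write_results(results: Sequence[ExtractionResult], path: str | Path) -> None:
    """Write one JSON record per document; lossless round-trip with
    :func:`read_results` (floats serialized at full repr precision)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for res in results:
            record = {
                "doc_id": res.doc_id,
                "config": res.config_used.to_dict(),
                "accepted": [e.to_dict() for e in res.accepted_entities],
                "rejected": [e.to_dict() for e in res.rejected_entities],
            }
            fh.write(json.dumps(record) + "\n")


def read_results(path: str | Path) -> list[ExtractionResult]:
    from .integrate import IntegrationConfig, MergedEntity

    path = Path(path)
    if not path.exists():
        raise InputError(f"results path does not exist: {path}")
    out: list[ExtractionResult] = []
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            record = json.loads(line)
            out.append(
                ExtractionResult(
                    doc_id=record["doc_id"],
                    accepted_entities=[MergedEntity.from_dict(e) for e in record["accepted"]],
                    rejected_entities=[MergedEntity.from_dict(e) for e in record["rejected"]],
                    config_used=IntegrationConfig.from_dict(record["config"]),
                )
            )
    return out
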