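"""Evaluation and hyperparameter tuning.

Predicted entities are matched one-to-one against gold annotations, code
matches before surface matches; per-document TP/FP/FN counts are
micro-aggregated (summed before computing metrics) into precision, recall
and F1. Two gold styles are supported:

* exhaustive gold (every true mention annotated): a prediction matching no
  gold annotation counts as a false positive;
* label-style gold (a fixed term list marked present/absent per document):
  a prediction matching an ``absent`` label is a false positive, and
  predictions matching no label at all are ignored.

The module also estimates per-extractor weights by sum-normalizing
held-out F1 scores, grid-searches the (kappa, gamma, theta)
hyperparameters, and decomposes residual error into FP and FN shares.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import POLARITY_PRESENT, GoldAnnotation
from .errors import DegenerateInputError, ValidationError
from .integrate import IntegrationConfig, MergedEntity, integrate
from .normalize import NormalizedTerm, deduplicate_entities, normalize_surface


@dataclass(frozen=True)
class OutcomeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("outcome counts must be non-negative")

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(counts: OutcomeCounts) -> Metrics:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F1 their harmonic mean.
    Any 0/0 is defined as 0."""
    p = _safe_div(counts.tp, counts.tp + counts.fp)
    r = _safe_div(counts.tp, counts.tp + counts.fn)
    return Metrics(precision=p, recall=r, f1=f1_score(r, p))


def f1_score(recall: float, precision: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    return _safe_div(2.0 * precision * recall, precision + recall)


def count_outcomes(
    predicted: Sequence[MergedEntity],
    gold: Sequence[GoldAnnotation],
    *,
    doc_id: str | None = None,
    unmatched_prediction_is_fp: bool = True,
) -> OutcomeCounts:
    """Greedy one-to-one matching of predicted entities against gold rows.

    A prediction matches a gold row when any member's primary code appears
    in the row's codes (code pass, run first) or when a member's normalized
    surface equals the row's normalized surface (fallback pass). Each gold
    row matches at most one prediction and vice versa.

    TP: matched rows with polarity present. FP: matched rows with polarity
    absent, plus — for exhaustive-style gold — predictions matching
    nothing. FN: present rows matched by no prediction.
    """
    if doc_id is not None:
        bad = [g.doc_id for g in gold if g.doc_id != doc_id]
        if bad:
            raise ValidationError(
                f"gold rows for {bad[0]!r} evaluated against document {doc_id!r}"
            )

    matched_gold: list[GoldAnnotation | None] = [None] * len(predicted)
    gold_taken = [False] * len(gold)

    # pass 1: code identity
    for pi, pred in enumerate(predicted):
        keys = pred.code_keys()
        for gi, ann in enumerate(gold):
            if gold_taken[gi] or not ann.codes:
                continue
            if keys & set(ann.codes):
                matched_gold[pi] = ann
                gold_taken[gi] = True
                break
    # pass 2: normalized surface
    for pi, pred in enumerate(predicted):
        if matched_gold[pi] is not None:
            continue
        surfaces = pred.surface_keys()
        for gi, ann in enumerate(gold):
            if gold_taken[gi] or not ann.surface:
                continue
            if normalize_surface(ann.surface) in surfaces:
                matched_gold[pi] = ann
                gold_taken[gi] = True
                break

    tp = sum(1 for ann in matched_gold if ann is not None and ann.polarity == POLARITY_PRESENT)
    fp = sum(1 for ann in matched_gold if ann is not None and ann.polarity != POLARITY_PRESENT)
    if unmatched_prediction_is_fp:
        fp += sum(1 for ann in matched_gold if ann is None)
    fn = sum(
        1
        for gi, ann in enumerate(gold)
        if ann.polarity == POLARITY_PRESENT and not gold_taken[gi]
    )
    return OutcomeCounts(tp=tp, fp=fp, fn=fn)


def aggregate(counts: Iterable[OutcomeCounts]) -> OutcomeCounts:
    """Micro-aggregation: element-wise sums of TP, FP, FN over documents."""
    total = OutcomeCounts()
    for c in counts:
        total = total + c
    return total


def macro_average(per_doc: Sequence[OutcomeCounts]) -> Metrics:
    """Mean of per-document metrics; exposed for comparison, micro is the
    default everywhere else."""
    if not per_doc:
        return Metrics(0.0, 0.0, 0.0)
    ms = [compute_metrics(c) for c in per_doc]
    n = len(ms)
    return Metrics(
        precision=sum(m.precision for m in ms) / n,
        recall=sum(m.recall for m in ms) / n,
        f1=sum(m.f1 for m in ms) / n,
    )


def estimate_extractor_weights(per_extractor_f1: Mapping[str, float]) -> dict[str, float]:
    """omega_i = f1_i / sum_j f1_j — held-out F1 scores sum-normalized into
    extractor weights."""
    if not per_extractor_f1:
        raise DegenerateInputError("no extractor F1 scores supplied")
    for ex, f1 in per_extractor_f1.items():
        if not 0.0 <= f1 <= 1.0:
            raise ValidationError(f"f1[{ex!r}] = {f1} outside [0, 1]")
    total = sum(per_extractor_f1.values())
    if total == 0.0:
        raise DegenerateInputError("all extractor F1 scores are zero")
    return {ex: f1 / total for ex, f1 in per_extractor_f1.items()}


def error_decomposition(counts: OutcomeCounts) -> tuple[float, float] | None:
    """(FP share, FN share) of residual error, or None when there is none."""
    total = counts.fp + counts.fn
    if total == 0:
        return None
    return (counts.fp / total, counts.fn / total)


# ---------------------------------------------------------------------------
# corpus-level evaluation and grid tuning

PerExtractorTerms = Mapping[str, Sequence[NormalizedTerm]]


def assemble_document(
    per_extractor_terms: PerExtractorTerms,
    config: IntegrationConfig,
    doc_id: str = "",
):
    """Negation filter (per kappa) -> per-extractor dedup -> integrate,
    for one document's flagged, normalized terms."""
    prepared = {}
    for ex_id, terms in per_extractor_terms.items():
        kept = [t for t in terms if not (config.kappa and t.term.negated)]
        prepared[ex_id] = deduplicate_entities(kept)
    return integrate(prepared, config, doc_id=doc_id)


def evaluate_run(
    per_doc_terms: Mapping[str, PerExtractorTerms],
    gold: Sequence[GoldAnnotation],
    config: IntegrationConfig,
    *,
    unmatched_prediction_is_fp: bool = True,
) -> tuple[OutcomeCounts, dict[str, OutcomeCounts]]:
    """Integrate and score every document; returns (micro totals, per-doc)."""
    gold_by_doc: dict[str, list[GoldAnnotation]] = {}
    for ann in gold:
        gold_by_doc.setdefault(ann.doc_id, []).append(ann)
    per_doc: dict[str, OutcomeCounts] = {}
    for doc_id in sorted(set(per_doc_terms) | set(gold_by_doc)):
        result = assemble_document(per_doc_terms.get(doc_id, {}), config, doc_id)
        per_doc[doc_id] = count_outcomes(
            result.accepted_entities,
            gold_by_doc.get(doc_id, []),
            doc_id=doc_id,
            unmatched_prediction_is_fp=unmatched_prediction_is_fp,
        )
    return aggregate(per_doc.values()), per_doc


@dataclass
class TuningGrid:
    """Full Cartesian product of hyperparameter values with per-cell metrics."""

    kappas: tuple[bool, ...]
    gammas: tuple[float, ...]
    thetas: tuple[float, ...]
    results: dict[tuple[bool, float, float], Metrics] = field(default_factory=dict)

    @property
    def best(self) -> tuple[tuple[bool, float, float], Metrics]:
        """Argmax-F1 cell; ties resolved toward smaller theta, then smaller
        gamma, then kappa=False."""
        return max(
            self.results.items(),
            key=lambda kv: (kv[1].f1, -kv[0][2], -kv[0][1], not kv[0][0]),
        )

    def to_rows(self) -> list[dict]:
        rows = []
        for (kappa, gamma, theta), m in sorted(self.results.items()):
            rows.append(
                {"kappa": kappa, "gamma": gamma, "theta": theta,
                 "precision": m.precision, "recall": m.recall, "f1": m.f1}
            )
        return rows

    def to_csv(self, path: str | Path) -> None:
        rows = self.to_rows()
        with Path(path).open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0]) if rows else
                                    ["kappa", "gamma", "theta", "precision", "recall", "f1"])
            writer.writeheader()
            writer.writerows(rows)


def grid_tune(
    per_doc_terms: Mapping[str, PerExtractorTerms],
    gold: Sequence[GoldAnnotation],
    omega: Mapping[str, float],
    *,
    kappas: Sequence[bool] = (False, True),
    gammas: Sequence[float] = (0.1,),
    thetas: Sequence[float] = (0.35,),
    unmatched_prediction_is_fp: bool = True,
) -> TuningGrid:
    """Run integration + evaluation over the full (kappa, gamma, theta)
    Cartesian product against one gold standard."""
    grid = TuningGrid(kappas=tuple(kappas), gammas=tuple(gammas), thetas=tuple(thetas))
    for kappa, gamma, theta in itertools.product(kappas, gammas, thetas):
        config = IntegrationConfig(kappa=kappa, gamma=gamma, theta=theta, omega=dict(omega))
        totals, _ = evaluate_run(
            per_doc_terms, gold, config,
            unmatched_prediction_is_fp=unmatched_prediction_is_fp,
        )
        grid.results[(kappa, gamma, theta)] = compute_metrics(totals)
    return grid
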