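"""Pipeline orchestration: extract -> negate -> normalize -> integrate -> evaluate.

The stage order is fixed: per-extractor extraction, negation flagging and
(per kappa) filtering, concept normalization, per-extractor deduplication,
then double-weight integration. A failing backend is logged and skipped;
the run fails only when every extractor fails. With mock backends the whole
pipeline is a pure function of its configuration, so repeated runs are
byte-identical.

A de-identification hook (``deidentifier``) is applied to each document
text before extraction; it defaults to the identity and exists as the
mount point for external anonymization tooling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import yaml

from .corpus import (
    Document,
    ExtractionResult,
    GoldAnnotation,
    read_corpus,
    read_gold,
    write_results,
)
from .errors import AllBackendsFailedError, ConfigurationError
from .evaluate import (
    OutcomeCounts,
    PerExtractorTerms,
    TuningGrid,
    aggregate,
    assemble_document,
    compute_metrics,
    count_outcomes,
    error_decomposition,
    grid_tune,
)
from .extractors import ExtractorSpec, run_ensemble
from .integrate import IntegrationConfig, uniform_omega
from .negation import NegationLexicon, detect_negation_spans, flag_negated, load_negation_lexicon
from .normalize import ConceptLexicon, encode_term

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs: inputs, roster, hyperparameters, outputs."""

    corpus_path: str | Path
    lexicon_path: str | Path
    extractors: list[ExtractorSpec]
    gold_path: str | Path | None = None
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    output_dir: str | Path | None = None
    negation_lexicon_path: str | Path | None = None
    unmatched_prediction_is_fp: bool = True
    deidentifier: Callable[[str], str] | None = None

    def __post_init__(self) -> None:
        if not self.extractors:
            raise ConfigurationError("extractor roster must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML or JSON config file; keyword overrides win."""
        raw = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(raw)
        specs = []
        for ex in data.get("extractors", []):
            specs.append(
                ExtractorSpec(
                    extractor_id=ex["extractor_id"],
                    kind=ex.get("kind", "mock"),
                    supported_categories=frozenset(
                        ex.get("supported_categories")
                        or ("medical_condition", "pharmaceutical_drug", "other")
                    ),
                    fixture=ex.get("fixture", {}),
                    endpoint=ex.get("endpoint"),
                    token=ex.get("token"),
                    type_mapping=ex.get("type_mapping", {}),
                    fail_message=ex.get("fail_message"),
                )
            )
        kwargs = dict(
            corpus_path=data["corpus_path"],
            lexicon_path=data["lexicon_path"],
            extractors=specs,
            gold_path=data.get("gold_path"),
            integration=IntegrationConfig.from_dict(data.get("integration", {})),
            output_dir=data.get("output_dir"),
            negation_lexicon_path=data.get("negation_lexicon_path"),
            unmatched_prediction_is_fp=data.get("unmatched_prediction_is_fp", True),
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _resolve_omega(config: PipelineConfig, extractor_ids: Sequence[str]) -> IntegrationConfig:
    integration = config.integration
    if not integration.omega:
        integration = IntegrationConfig(
            kappa=integration.kappa,
            gamma=integration.gamma,
            theta=integration.theta,
            omega=uniform_omega(list(extractor_ids)),
        )
    return integration


def prepare_terms(
    config: PipelineConfig,
) -> tuple[list[Document], dict[str, PerExtractorTerms], ConceptLexicon, list[str]]:
    """Run extraction + negation flagging + normalization (no kappa filter,
    no dedup yet) and return per-document, per-extractor flagged terms.

    This is the shared front half of extract/evaluate/tune: the kappa
    filter and per-extractor dedup are applied per integration config so a
    tuning grid can sweep kappa without re-extracting.
    """
    documents = read_corpus(config.corpus_path)
    if config.deidentifier is not None:
        documents = [
            Document(doc_id=d.doc_id, text=config.deidentifier(d.text), metadata=d.metadata)
            for d in documents
        ]
    lexicon = ConceptLexicon.from_json(config.lexicon_path)
    neg_lexicon: NegationLexicon = load_negation_lexicon(config.negation_lexicon_path)

    outputs, failed = run_ensemble(documents, config.extractors)
    if not outputs:
        raise AllBackendsFailedError(
            f"all extractors failed: {', '.join(failed)}"
        )

    per_doc: dict[str, PerExtractorTerms] = {}
    for doc in documents:
        spans = detect_negation_spans(doc.text, neg_lexicon)
        per_extractor: dict[str, list] = {}
        for ex_id in sorted(outputs):
            raw = outputs[ex_id].get(doc.doc_id, [])
            flagged = flag_negated(raw, spans, text=doc.text)
            per_extractor[ex_id] = [encode_term(t, lexicon) for t in flagged]
        per_doc[doc.doc_id] = per_extractor
        log.info(
            "doc %s: %d terms extracted, %d negated",
            doc.doc_id,
            sum(len(v) for v in per_extractor.values()),
            sum(t.term.negated for v in per_extractor.values() for t in v),
        )
    return documents, per_doc, lexicon, failed


def run_extract(config: PipelineConfig) -> tuple[list[ExtractionResult], dict[str, PerExtractorTerms]]:
    """Full extraction pipeline.

    Returns the integrated view (one :class:`ExtractionResult` per
    document) alongside the raw per-extractor view, and writes
    ``results.jsonl`` when an output directory is configured.
    """
    documents, per_doc, _, _ = prepare_terms(config)
    integration = _resolve_omega(config, [e.extractor_id for e in config.extractors])
    results = [
        assemble_document(per_doc[doc.doc_id], integration, doc_id=doc.doc_id)
        for doc in documents
    ]
    for res in results:
        log.info(
            "doc %s: %d accepted, %d rejected",
            res.doc_id, len(res.accepted_entities), len(res.rejected_entities),
        )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_results(results, out / "results.jsonl")
    return results, per_doc


def evaluate_results(
    results: Sequence[ExtractionResult],
    gold: Sequence[GoldAnnotation],
    *,
    unmatched_prediction_is_fp: bool = True,
) -> dict:
    """Score persisted or in-memory results against gold; JSON-ready report."""
    gold_by_doc: dict[str, list[GoldAnnotation]] = {}
    for ann in gold:
        gold_by_doc.setdefault(ann.doc_id, []).append(ann)
    per_doc = {}
    for res in results:
        counts = count_outcomes(
            res.accepted_entities,
            gold_by_doc.get(res.doc_id, []),
            doc_id=res.doc_id,
            unmatched_prediction_is_fp=unmatched_prediction_is_fp,
        )
        per_doc[res.doc_id] = {"tp": counts.tp, "fp": counts.fp, "fn": counts.fn}
    totals = aggregate(OutcomeCounts(**c) for c in per_doc.values())
    metrics = compute_metrics(totals)
    shares = error_decomposition(totals)
    return {
        "per_document": per_doc,
        "totals": {"tp": totals.tp, "fp": totals.fp, "fn": totals.fn},
        "micro": {"precision": metrics.precision, "recall": metrics.recall, "f1": metrics.f1},
        "error_shares": (
            {"fp_share": shares[0], "fn_share": shares[1]} if shares else None
        ),
    }


def run_evaluate(config: PipelineConfig) -> dict:
    """Extract and score against the configured gold standard."""
    if config.gold_path is None:
        raise ConfigurationError("evaluation requires a gold_path")
    gold = read_gold(config.gold_path)
    results, _ = run_extract(config)
    report = evaluate_results(
        results, gold, unmatched_prediction_is_fp=config.unmatched_prediction_is_fp
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1), encoding="utf-8")
    return report


def run_tune(
    config: PipelineConfig,
    *,
    kappas: Sequence[bool] = (False, True),
    gammas: Sequence[float] = (0.1,),
    thetas: Sequence[float] = (0.35,),
) -> TuningGrid:
    """Grid-search (kappa, gamma, theta) against the gold standard and
    persist the grid plus the best cell."""
    if config.gold_path is None:
        raise ConfigurationError("tuning requires a gold_path")
    gold = read_gold(config.gold_path)
    _, per_doc, _, _ = prepare_terms(config)
    integration = _resolve_omega(config, [e.extractor_id for e in config.extractors])
    grid = grid_tune(
        per_doc,
        gold,
        integration.omega,
        kappas=kappas,
        gammas=gammas,
        thetas=thetas,
        unmatched_prediction_is_fp=config.unmatched_prediction_is_fp,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        grid.to_csv(out / "grid.csv")
        (best_cell, best_metrics) = grid.best
        (out / "grid_best.json").write_text(
            json.dumps(
                {
                    "kappa": best_cell[0], "gamma": best_cell[1], "theta": best_cell[2],
                    "precision": best_metrics.precision,
                    "recall": best_metrics.recall,
                    "f1": best_metrics.f1,
                },
                indent=1,
            ),
            encoding="utf-8",
        )
    return grid
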