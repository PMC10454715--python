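"""End-to-end orchestration: MAF pre-filter, criterion assignment, ACMG
combination, sample-level P_POT attachment and segregation substitution."""

from __future__ import annotations

import logging
from typing import Any, Optional

from .combine import classify_variant
from .criteria import assign_criteria, decision_maf
from .io import InputRecord, parse_upstream_call
from .model import (
    AcmgClass,
    ClassifiedVariant,
    EvidenceSet,
    GeneInfo,
    SampleContext,
    ThresholdConfig,
    VariantAnnotation,
    Verdict,
    VusSubclass,
)
from .ppot import SegregationResult, apply_ppot, resolve_segregation

logger = logging.getLogger(__name__)


def filtered_verdict(maf: float, cfg: ThresholdConfig) -> Verdict:
    return Verdict(
        acmg_class=AcmgClass.FILTERED,
        vus_subclass=VusSubclass.NONE,
        reportable=False,
        evidence=EvidenceSet(),
        explanation=(
            f"decision MAF {maf:g} is not below {cfg.decision_maf_pct:g}%; "
            "variant filtered before classification",
        ),
    )


def classify_annotation(
    variant: VariantAnnotation,
    cfg: ThresholdConfig,
    user_calls: Optional[list[dict[str, Any]]] = None,
) -> Verdict:
    """Classify one variant (without sample-level P_POT logic)."""
    maf, passes = decision_maf(variant.population, cfg)
    if not passes:
        return filtered_verdict(maf, cfg)
    evidence = assign_criteria(variant, cfg)
    for raw in user_calls or []:
        call = parse_upstream_call(raw).model_copy(update={"source": "user"})
        logger.info("user confirmation: %s -> %s", call.criterion.value, call.strength)
        evidence = evidence.with_call(call)
    return classify_variant(evidence)


def classify_records(
    records: list[InputRecord],
    gene_table: dict[str, GeneInfo],
    cfg: Optional[ThresholdConfig] = None,
    segregation: Optional[dict[tuple[str, str, str], SegregationResult]] = None,
    edits: Optional[dict[tuple[str, str], list[dict[str, Any]]]] = None,
) -> list[SampleContext]:
    """Run the full pipeline and return one context per sample, in order of
    first appearance."""
    cfg = cfg or ThresholdConfig()
    by_sample: dict[str, list[ClassifiedVariant]] = {}
    for record in records:
        annotation = record.to_annotation(gene_table)
        verdict = classify_annotation(
            annotation, cfg, (edits or {}).get((record.sample_id, annotation.hgvs_c))
        )
        by_sample.setdefault(record.sample_id, []).append(
            ClassifiedVariant(annotation=annotation, verdict=verdict)
        )

    contexts = []
    for sample_id, variants in by_sample.items():
        ctx = apply_ppot(SampleContext(sample_id=sample_id, variants=tuple(variants)))
        if segregation:
            updated = []
            for entry in ctx.variants:
                key = (sample_id, entry.annotation.gene.symbol, entry.annotation.hgvs_c)
                result = segregation.get(key)
                if result is not None and entry.verdict.ppot is not None:
                    updated.append(
                        ClassifiedVariant(
                            annotation=entry.annotation,
                            verdict=resolve_segregation(
                                entry.annotation, entry.verdict, result
                            ),
                        )
                    )
                else:
                    if result is not None:
                        logger.info(
                            "segregation result for %s ignored: no met P_POT", key
                        )
                    updated.append(entry)
            ctx = SampleContext(sample_id=sample_id, variants=tuple(updated))
        contexts.append(ctx)
    return contexts
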