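"""Automatic criterion assignment and strength modification.

Implements the criteria the engine computes itself — the PP3/BP4 in-silico
rules with their per-consequence branches, the PM2 and BP6 strength
re-assignments, the BP1 gene-statistic rule and the decision-MAF pre-filter
— and merges them with upstream-attributed calls into one evidence set.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict

from .model import (
    ConsequenceClass,
    Criterion,
    EvidenceCall,
    EvidenceSet,
    GeneInfo,
    LOF_CONSEQUENCES,
    Polarity,
    PopulationData,
    PredictorScores,
    StrengthLevel,
    ThresholdConfig,
    VariantAnnotation,
    parse_strength,
)
from .pvs1 import classify_pvs1

logger = logging.getLogger(__name__)

#: Criteria whose upstream attribution is always replaced by the engine.
ENGINE_OWNED = frozenset({Criterion.PP3, Criterion.BP4, Criterion.PM2, Criterion.BP1, Criterion.PVS1})

#: Consequence classes evaluated by the missense arm of PP3/BP4.
_MISSENSE_LIKE = frozenset({ConsequenceClass.MISSENSE, ConsequenceClass.MISSENSE_SPLICE})

#: Consequence classes evaluated purely on the splice AdaBoost/RF scores.
_SPLICE_ONLY = frozenset(
    {
        ConsequenceClass.SYNONYMOUS_SPLICE,
        ConsequenceClass.SPLICE_REGION,
        ConsequenceClass.INTRONIC_WITHIN_5,
    }
)


class Pp3Bp4Decision(BaseModel):
    model_config = ConfigDict(frozen=True)

    verdict: Literal["pp3_met", "bp4_met", "neither", "not_applicable"]
    conditions_met: dict[str, bool] = {}
    branch: Optional[Literal["missense", "missense_fallback_splice", "splice_scores"]] = None
    rationale: str = ""


def count_rank_scores(
    scores: PredictorScores, cutoff: float, direction: Literal["ge", "le"]
) -> tuple[int, int]:
    """Count available rank scores satisfying the comparison.

    Returns ``(count, n_available)``; comparisons are inclusive at the cutoff.
    """
    values = list(scores.rank_scores.values())
    if direction == "ge":
        count = sum(1 for v in values if v >= cutoff)
    else:
        count = sum(1 for v in values if v <= cutoff)
    return count, len(values)


def _missense_conditions(
    scores: PredictorScores, cfg: ThresholdConfig, side: Literal["path", "benign"]
) -> dict[str, Optional[bool]]:
    """Evaluate the three missense conditions; ``None`` marks a condition
    whose inputs are entirely missing (not evaluable)."""
    if side == "path":
        revel = None if scores.revel is None else scores.revel >= cfg.revel_path
        cadd = None if scores.cadd_phred is None else scores.cadd_phred >= cfg.cadd_path
        count, n_avail = count_rank_scores(scores, cfg.rank_cutoff_path, "ge")
    else:
        revel = None if scores.revel is None else scores.revel <= cfg.revel_benign
        cadd = None if scores.cadd_phred is None else scores.cadd_phred <= cfg.cadd_benign
        count, n_avail = count_rank_scores(scores, cfg.rank_cutoff_benign, "le")
    rank = None if n_avail == 0 else count >= cfg.n_rank_required
    return {"revel": revel, "cadd": cadd, "rank_majority": rank}


def _splice_condition(
    scores: PredictorScores, cfg: ThresholdConfig, side: Literal["path", "benign"]
) -> bool:
    if scores.ada_boost is None or scores.rf is None:
        return False
    if side == "path":
        return scores.ada_boost >= cfg.ada_cutoff and scores.rf >= cfg.rf_cutoff
    return scores.ada_boost <= cfg.ada_cutoff and scores.rf <= cfg.rf_cutoff


def _splice_boundary_conflict(scores: PredictorScores, cfg: ThresholdConfig) -> bool:
    # Both printed inequalities are non-strict, so exact cutoff equality on
    # both scores satisfies the pathogenic and benign rule simultaneously.
    return _splice_condition(scores, cfg, "path") and _splice_condition(scores, cfg, "benign")


def _decide(
    side: Literal["path", "benign"],
    consequence: ConsequenceClass,
    scores: PredictorScores,
    cfg: ThresholdConfig,
) -> Pp3Bp4Decision:
    met_verdict = "pp3_met" if side == "path" else "bp4_met"
    if consequence in _MISSENSE_LIKE:
        conds = _missense_conditions(scores, cfg, side)
        n_evaluable = sum(1 for v in conds.values() if v is not None)
        flat = {k: bool(v) for k, v in conds.items()}
        if consequence is ConsequenceClass.MISSENSE or n_evaluable >= 2:
            n_true = sum(flat.values())
            met = n_true >= 2
            return Pp3Bp4Decision(
                verdict=met_verdict if met else "neither",
                conditions_met={**flat, "ada_rf": False},
                branch="missense",
                rationale=f"{n_true}/3 missense conditions satisfied",
            )
        # missense+splice fallback: too few missense inputs to judge
        branch = "missense_fallback_splice"
    elif consequence in _SPLICE_ONLY:
        branch = "splice_scores"
    else:
        return Pp3Bp4Decision(verdict="not_applicable")

    if _splice_boundary_conflict(scores, cfg):
        return Pp3Bp4Decision(
            verdict="neither",
            conditions_met={"ada_rf": False},
            branch=branch,
            rationale=(
                "conflict: AdaBoost/RF scores sit exactly at the cutoffs, satisfying "
                "both the pathogenic and the benign splice rule; neither is assigned"
            ),
        )
    met = _splice_condition(scores, cfg, side)
    return Pp3Bp4Decision(
        verdict=met_verdict if met else "neither",
        conditions_met={"ada_rf": met},
        branch=branch,
        rationale="splice AdaBoost/RF rule",
    )


def assign_pp3(
    consequence: ConsequenceClass, scores: PredictorScores, cfg: ThresholdConfig
) -> Pp3Bp4Decision:
    """PP3: missense needs ≥2/3 of {REVEL, CADD, rank-score majority} at the
    pathogenic cutoffs; splice classes need AdaBoost AND RF above cutoff."""
    return _decide("path", consequence, scores, cfg)


def assign_bp4(
    consequence: ConsequenceClass, scores: PredictorScores, cfg: ThresholdConfig
) -> Pp3Bp4Decision:
    """BP4: mirror of :func:`assign_pp3` with the benign cutoffs."""
    return _decide("benign", consequence, scores, cfg)


def _fmt(x: float) -> str:
    return f"{x:g}"


def pp3_bp4_calls(
    consequence: ConsequenceClass, scores: PredictorScores, cfg: ThresholdConfig
) -> tuple[Optional[EvidenceCall], Optional[EvidenceCall]]:
    """Evaluate both rules and render them as evidence calls with rationales
    in the style of the diagnostic checklist; returns ``(pp3, bp4)`` where an
    entry is ``None`` when the rule does not apply to the consequence."""
    pp3 = assign_pp3(consequence, scores, cfg)
    bp4 = assign_bp4(consequence, scores, cfg)
    if pp3.verdict == "not_applicable":
        return None, None

    count, n_avail = count_rank_scores(scores, cfg.rank_cutoff_path, "ge")
    revel = scores.revel
    cadd = scores.cadd_phred
    parts = [f"{count}/{cfg.n_rank_total} predictors are damaging"]
    if revel is not None:
        op = ">" if revel > cfg.revel_path else ("<" if revel < cfg.revel_path else "=")
        parts.append(f"REVEL score: {_fmt(revel)} ({op}{_fmt(cfg.revel_path)})")
    if cadd is not None:
        op = ">" if cadd > cfg.cadd_path else ("<" if cadd < cfg.cadd_path else "=")
        parts.append(f"CADD score: {_fmt(cadd)} ({op}{_fmt(cfg.cadd_path)})")
    if pp3.branch in ("missense_fallback_splice", "splice_scores"):
        parts = [
            f"AdaBoost score: {'' if scores.ada_boost is None else _fmt(scores.ada_boost)}"
            f" (cutoff {_fmt(cfg.ada_cutoff)}), RF score:"
            f" {'' if scores.rf is None else _fmt(scores.rf)} (cutoff {_fmt(cfg.rf_cutoff)})"
        ]
    detail = ", ".join(parts)

    pp3_call = EvidenceCall(
        criterion=Criterion.PP3,
        met=pp3.verdict == "pp3_met",
        strength=StrengthLevel.PP if pp3.verdict == "pp3_met" else None,
        rationale=(pp3.rationale + ": " if pp3.rationale else "") + detail,
        source="auto",
    )
    bp4_call = EvidenceCall(
        criterion=Criterion.BP4,
        met=bp4.verdict == "bp4_met",
        strength=StrengthLevel.BP if bp4.verdict == "bp4_met" else None,
        rationale=(bp4.rationale + ": " if bp4.rationale else "") + detail,
        source="auto",
    )
    return pp3_call, bp4_call


PM2_RATIONALE = (
    "Absent from controls (or at extremely low frequency if recessive) in Exome "
    "Sequencing Project, 1000 Genomes Project, or Exome Aggregation Consortium."
)


def modify_pm2(triggered: bool, upstream_strength: Optional[StrengthLevel] = None) -> EvidenceCall:
    """PM2 is re-assigned the standard Moderate intensity whenever triggered,
    regardless of the upstream (Supporting/Strong) strength."""
    if not triggered:
        return EvidenceCall(criterion=Criterion.PM2, met=False, rationale="Not triggered")
    return EvidenceCall(
        criterion=Criterion.PM2,
        met=True,
        strength=StrengthLevel.PM,
        rationale=PM2_RATIONALE,
        source="auto",
    )


def modify_bp6(triggered: bool, upstream_label: Optional[str] = None) -> EvidenceCall:
    """BP6 triggered at a Very Strong or Moderate level is re-assigned a
    Supporting intensity; Strong and Supporting pass through unchanged.

    ``upstream_label`` is the raw upstream strength label (VarSome may report
    levels outside the benign lattice); a later user confirmation may upgrade
    Supporting to Strong (see the ``confirm`` CLI subcommand).
    """
    if not triggered:
        return EvidenceCall(criterion=Criterion.BP6, met=False, rationale="Not triggered")
    norm = (upstream_label or "supporting").replace("_", "").replace(" ", "").lower()
    if norm in ("verystrong", "moderate"):
        return EvidenceCall(
            criterion=Criterion.BP6,
            met=True,
            strength=StrengthLevel.BP,
            rationale=f"Re-assigned Supporting (upstream {upstream_label}); "
            "strength confirmation by the geneticist may upgrade to Strong",
            source="auto",
        )
    strength = parse_strength(norm, Polarity.BENIGN)
    return EvidenceCall(
        criterion=Criterion.BP6,
        met=True,
        strength=strength,
        rationale=f"Kept at upstream strength {strength.label}",
        source="upstream",
    )


def benign_fraction_pct(benign: int, total: int) -> float:
    """Percentage of non-VUS missense variants classified benign, rounded to
    one decimal, half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(100 * benign) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def assign_bp1(
    gene: GeneInfo, consequence: ConsequenceClass, cfg: ThresholdConfig
) -> EvidenceCall:
    """BP1 for missense variants, via the benign-fraction rule or (per-gene
    opt-in) the missense-Z rule."""
    not_met = EvidenceCall(criterion=Criterion.BP1, met=False, rationale="Not applicable")
    if consequence not in _MISSENSE_LIKE:
        return not_met
    b, t = gene.benign_nonvus_missense, gene.total_nonvus_missense
    if b is not None and t is not None and t > 0:
        pct = benign_fraction_pct(b, t)
        if pct > cfg.bp1_benign_fraction_pct:
            return EvidenceCall(
                criterion=Criterion.BP1,
                met=True,
                strength=StrengthLevel.BP,
                rationale=(
                    f"{b} out of {t} non-VUS missense variants in gene {gene.symbol} are "
                    f"benign = {pct}%, which is more than threshold of "
                    f"{_fmt(cfg.bp1_benign_fraction_pct)}%"
                ),
                source="auto",
            )
    if (
        gene.symbol in cfg.bp1_missense_z_genes
        and gene.missense_z is not None
        and gene.missense_z < cfg.bp1_missense_z
    ):
        return EvidenceCall(
            criterion=Criterion.BP1,
            met=True,
            strength=StrengthLevel.BP,
            rationale=(
                f"GnomAD missense Z-score for gene {gene.symbol} is {_fmt(gene.missense_z)}, "
                f"which is less than {_fmt(cfg.bp1_missense_z)}"
            ),
            source="auto",
        )
    return not_met


def decision_maf(population: PopulationData, cfg: ThresholdConfig) -> tuple[float, bool]:
    """Integrate per-source frequencies (maximum) into one decision MAF;
    variants at or above the threshold are filtered before classification."""
    maf = max(population.maf_by_source.values(), default=0.0)
    return maf, maf < cfg.decision_maf_pct / 100.0


def pm2_triggered_auto(variant: VariantAnnotation) -> bool:
    """Fallback PM2 trigger used when no upstream PM2 call is supplied:
    absence from all present population sources, or (for AR genes) fewer than
    two homozygotes in gnomAD; vetoed by known-bad coverage."""
    pop = variant.population
    if pop.coverage_ok is False:
        return False
    absent = all(f == 0.0 for f in pop.maf_by_source.values()) and pop.gnomad_allele_count in (
        None,
        0,
    )
    if absent:
        return True
    if (
        "AR" in variant.gene.inheritance
        and pop.gnomad_hom_count is not None
        and pop.gnomad_hom_count < 2
    ):
        return True
    return False


def assign_criteria(variant: VariantAnnotation, cfg: ThresholdConfig) -> EvidenceSet:
    """Merge engine-computed criteria with upstream attributions.

    Engine-owned criteria (PP3, BP4, PM2, BP1, PVS1) override any upstream
    call for the same code; every override is logged. BP6 strength
    modification is applied to upstream BP6 calls and PP5 is capped at
    Supporting.
    """
    calls: dict[Criterion, EvidenceCall] = {}
    upstream = {c.criterion: c for c in variant.upstream_calls}

    pp3_call, bp4_call = pp3_bp4_calls(variant.consequence, variant.scores, cfg)
    if pp3_call is not None:
        calls[Criterion.PP3] = pp3_call
        calls[Criterion.BP4] = bp4_call

    calls[Criterion.BP1] = assign_bp1(variant.gene, variant.consequence, cfg)

    if Criterion.PM2 in upstream:
        up = upstream[Criterion.PM2]
        calls[Criterion.PM2] = modify_pm2(up.met, up.strength)
    else:
        calls[Criterion.PM2] = modify_pm2(pm2_triggered_auto(variant))

    if variant.lof is not None and variant.consequence in LOF_CONSEQUENCES:
        result = classify_pvs1(variant.lof, variant.gene)
        calls[Criterion.PVS1] = EvidenceCall(
            criterion=Criterion.PVS1,
            met=result.met,
            strength=result.strength,
            rationale=result.rationale,
            source="auto",
        )

    for criterion, call in upstream.items():
        if criterion in ENGINE_OWNED:
            engine = calls.get(criterion)
            logger.info(
                "override: %s upstream %s replaced by engine %s",
                criterion.value,
                call.strength.value if call.strength else "not-met",
                engine.strength.value if engine is not None and engine.strength else "not-met",
            )
            continue
        if criterion is Criterion.BP6:
            calls[criterion] = modify_bp6(
                call.met, call.strength.label if call.strength else None
            )
        elif criterion is Criterion.PP5 and call.met and call.strength is not StrengthLevel.PP:
            calls[criterion] = call.model_copy(
                update={
                    "strength": StrengthLevel.PP,
                    "rationale": (call.rationale + " " if call.rationale else "")
                    + "[capped at Supporting]",
                }
            )
            logger.info("PP5 upstream %s capped at Supporting", call.strength.value)
        else:
            calls[criterion] = call

    ordered = sorted(calls.values(), key=lambda c: list(Criterion).index(c.criterion))
    return EvidenceSet(calls=tuple(ordered))
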