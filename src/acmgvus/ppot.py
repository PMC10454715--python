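"""Sample-aware pathogenicity-potential (P_POT) logic.

Middle VUS that could rise to likely pathogenic after segregation testing
receive a proxy criterion: eligibility depends on inheritance mode,
zygosity and the other variants carried by the same individual; the
strength is Moderate with a defined downgrade to Supporting; once real
segregation results arrive the proxy is replaced by the corresponding
ACMG criterion (or its benign counterpart).
"""

from __future__ import annotations

import logging
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .combine import classify_variant
from .model import (
    AcmgClass,
    ClassifiedVariant,
    Criterion,
    EvidenceCall,
    SampleContext,
    StrengthCounts,
    StrengthLevel,
    VariantAnnotation,
    Verdict,
    VusSubclass,
    effective_counts,
)

logger = logging.getLogger(__name__)


class SegregationResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: Literal[
        "de_novo_confirmed",
        "de_novo_excluded",
        "in_trans_confirmed",
        "in_cis_or_refuted",
        "cosegregation_confirmed",
        "cosegregation_refuted",
    ]
    meioses: Optional[int] = Field(default=None, ge=0)
    parentage_confirmed: bool = False
    #: genotype also observed in an unaffected relative (adds BS2)
    observed_in_healthy: bool = False


def _qualifies_as_partner(verdict: Verdict) -> bool:
    return verdict.acmg_class in (AcmgClass.P, AcmgClass.LP) or (
        verdict.acmg_class is AcmgClass.VUS
        and verdict.vus_subclass in (VusSubclass.HOT, VusSubclass.MIDDLE)
    )


def _partner_label(verdict: Verdict) -> str:
    return {
        AcmgClass.P: "pathogenic",
        AcmgClass.LP: "likely pathogenic",
    }.get(verdict.acmg_class, f"{verdict.vus_subclass.value} VUS")


def ppot_eligible(
    variant: VariantAnnotation, verdict: Verdict, context: SampleContext
) -> tuple[bool, Optional[int], str]:
    """Decide whether a Middle VUS receives P_POT; returns the lowest
    satisfied condition number (1–4) and a report-style rationale.

    Conditions: (1) another P/LP/Hot/Middle-VUS variant in the same AR gene
    in the same individual; (2) homozygous in an AR gene; (3) heterozygous
    in an AD gene; (4) hemizygous in an X-linked gene.
    """
    if not (verdict.acmg_class is AcmgClass.VUS and verdict.vus_subclass is VusSubclass.MIDDLE):
        return False, None, "not a Middle VUS"
    inheritance = variant.gene.inheritance
    if not inheritance:
        logger.warning(
            "gene %s has no inheritance mode; P_POT not assessable", variant.gene.symbol
        )
        return False, None, f"no inheritance mode known for gene {variant.gene.symbol}"

    if "AR" in inheritance:
        for other in context.by_gene(variant.gene.symbol):
            same = (
                other.annotation.transcript == variant.transcript
                and other.annotation.hgvs_c == variant.hgvs_c
            )
            if same or not _qualifies_as_partner(other.verdict):
                continue
            return (
                True,
                1,
                "possible in-trans configuration with the "
                f"{_partner_label(other.verdict)} {other.annotation.annotation} variant",
            )
        if variant.zygosity == "hom":
            return (
                True,
                2,
                "homozygous variant in a gene associated with an autosomal recessive disorder",
            )
    if "AD" in inheritance and variant.zygosity == "het":
        return True, 3, "possible de novo variant"
    if "XL" in inheritance and variant.zygosity == "hemi":
        return (
            True,
            4,
            "hemizygous variant in a gene associated with an X-linked condition",
        )
    return False, None, "no eligibility condition satisfied"


def ppot_strength(counts: StrengthCounts) -> StrengthLevel:
    """Moderate by default; downgraded to Supporting for the (1 PM + 2 PP)
    and (2 PM) pathogenic combinations. Benign counts are ignored."""
    if (counts.pm == 1 and counts.pp == 2) or counts.pm == 2:
        return StrengthLevel.PP
    return StrengthLevel.PM


def apply_ppot(context: SampleContext) -> SampleContext:
    """Attach P_POT to every eligible Middle VUS and re-subclassify.

    Eligibility is judged single-pass on the P_POT-free verdicts, so two
    Middle VUS in the same recessive gene each see the other as a partner.
    A promoted variant always ends up Hot: the augmented pattern is looked
    up in the subclass table and, when absent, promotion is applied
    directly.
    """
    updated: list[ClassifiedVariant] = []
    for entry in context.variants:
        variant, verdict = entry.annotation, entry.verdict
        eligible, condition, rationale = ppot_eligible(variant, verdict, context)
        if not eligible:
            updated.append(entry)
            continue
        strength = ppot_strength(effective_counts(verdict.evidence, include_ppot=False))
        call = EvidenceCall(
            criterion=Criterion.PPOT,
            met=True,
            strength=strength,
            rationale=rationale,
            source="auto",
        )
        new_verdict = classify_variant(verdict.evidence.with_call(call))
        if new_verdict.vus_subclass is not VusSubclass.HOT:
            logger.info(
                "%s: P_POT-augmented pattern not Hot via lookup; promoting directly",
                variant.annotation,
            )
            new_verdict = Verdict(
                acmg_class=new_verdict.acmg_class,
                vus_subclass=VusSubclass.HOT,
                ppot=call,
                reportable=True,
                evidence=new_verdict.evidence,
                explanation=new_verdict.explanation
                + ("promoted directly to Hot by P_POT (augmented pattern unprinted)",),
            )
        updated.append(
            ClassifiedVariant(
                annotation=variant,
                verdict=new_verdict.model_copy(
                    update={
                        "explanation": new_verdict.explanation
                        + (f"P_POT condition {condition}: {rationale} [Hot (potential)]",)
                    }
                ),
            )
        )
    return SampleContext(sample_id=context.sample_id, variants=tuple(updated))


#: Replacement criteria once segregation results are available.
_SEGREGATION_CRITERIA = {
    "in_trans_confirmed": (Criterion.PM3, StrengthLevel.PM, "confirmed in-trans configuration"),
    "cosegregation_confirmed": (
        Criterion.PP1,
        StrengthLevel.PP,
        "cosegregation with disease in affected family members",
    ),
    "de_novo_excluded": (Criterion.BS4, StrengthLevel.BS, "de novo occurrence excluded"),
    "in_cis_or_refuted": (
        Criterion.BP2,
        StrengthLevel.BP,
        "variants found in cis (or in-trans configuration refuted)",
    ),
    "cosegregation_refuted": (
        Criterion.BS4,
        StrengthLevel.BS,
        "lack of segregation in affected members of the family",
    ),
}


def resolve_segregation(
    variant: VariantAnnotation, verdict: Verdict, result: SegregationResult
) -> Verdict:
    """Substitute a met P_POT with the criterion the segregation result
    establishes and reclassify from scratch."""
    ppot = verdict.evidence.get(Criterion.PPOT)
    if ppot is None or not ppot.met:
        raise ValueError("resolve_segregation requires a verdict carrying a met P_POT")
    evidence = verdict.evidence.without(Criterion.PPOT)

    if result.kind == "de_novo_confirmed":
        if result.parentage_confirmed:
            crit, strength, why = Criterion.PS2, StrengthLevel.PS, "confirmed de novo (parentage confirmed)"
        else:
            crit, strength, why = Criterion.PM6, StrengthLevel.PM, "de novo without confirmation of parentage"
    else:
        crit, strength, why = _SEGREGATION_CRITERIA[result.kind]
    if result.meioses:
        why += f" ({result.meioses} meioses)"
    evidence = evidence.with_call(
        EvidenceCall(criterion=crit, met=True, strength=strength, rationale=why, source="user")
    )
    if result.observed_in_healthy:
        evidence = evidence.with_call(
            EvidenceCall(
                criterion=Criterion.BS2,
                met=True,
                strength=StrengthLevel.BS,
                rationale="genotype observed in a healthy adult relative",
                source="user",
            )
        )
    new_verdict = classify_variant(evidence)
    return new_verdict.model_copy(
        update={
            "explanation": new_verdict.explanation
            + (f"P_POT inactivated and substituted by {crit.value} ({result.kind})",)
        }
    )
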