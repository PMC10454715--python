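"""Curated worked-example cases and a seeded synthetic record generator.

The four builtin cases carry the full structured input for one variant
each (one of them with a second, pathogenic variant in the same sample)
together with the expected evidence calls and final verdict. Individual
rank scores not printed in the source material are synthesized so that
the printed aggregate (e.g. "11/15 damaging") holds exactly.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterator, Literal, Optional

from pydantic import BaseModel, ConfigDict

from .model import (
    AcmgClass,
    ClinVarSummary,
    ConsequenceClass,
    Criterion,
    EvidenceCall,
    EvidenceSet,
    GeneInfo,
    LoFAnnotation,
    PopulationData,
    PredictorScores,
    RANK_PREDICTORS,
    SampleContext,
    StrengthCounts,
    StrengthLevel,
    ThresholdConfig,
    VariantAnnotation,
    Verdict,
    VusSubclass,
)


class FixtureCase(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    annotation: VariantAnnotation
    #: other variants carried by the same sample (partner variants)
    context_annotations: tuple[VariantAnnotation, ...] = ()
    config: ThresholdConfig
    expected_evidence: EvidenceSet
    expected_verdict: Verdict
    citation: str = ""


def make_rank_scores(
    n_damaging: int, damaging: float = 0.75, benign: float = 0.20
) -> dict[str, float]:
    """Synthesize the 15 rank scores so exactly ``n_damaging`` sit above the
    pathogenic cutoff (the published aggregates, not the individual values,
    drive every rule)."""
    return {
        name: (damaging if i < n_damaging else benign)
        for i, name in enumerate(RANK_PREDICTORS)
    }


FIXTURE_CONFIG = ThresholdConfig(bp1_missense_z_genes=("SERPINA6",))

GENES = {
    "SERPINA6": GeneInfo(symbol="SERPINA6", inheritance=frozenset({"AR"}), missense_z=-0.662),
    "TYR": GeneInfo(symbol="TYR", inheritance=frozenset({"AR"}), lof_mechanism=True),
    "USH2A": GeneInfo(
        symbol="USH2A",
        inheritance=frozenset({"AR"}),
        benign_nonvus_missense=196,
        total_nonvus_missense=529,
        lof_mechanism=True,
    ),
    "CELSR1": GeneInfo(
        symbol="CELSR1",
        inheritance=frozenset({"AD"}),
        benign_nonvus_missense=33,
        total_nonvus_missense=33,
    ),
}


def _call(criterion: Criterion, strength: StrengthLevel, **kw) -> EvidenceCall:
    return EvidenceCall(criterion=criterion, met=True, strength=strength, **kw)


def _upstream(criterion: str, strength: str, rationale: str = "") -> EvidenceCall:
    crit = Criterion(criterion)
    from .model import parse_strength

    return EvidenceCall(
        criterion=crit,
        met=True,
        strength=parse_strength(strength, crit.polarity),
        rationale=rationale,
        source="upstream",
    )


def _expected(
    calls: list[EvidenceCall],
    acmg: AcmgClass,
    subclass: VusSubclass,
    reportable: bool,
) -> tuple[EvidenceSet, Verdict]:
    evidence = EvidenceSet(calls=tuple(calls))
    ppot = evidence.get(Criterion.PPOT)
    verdict = Verdict(
        acmg_class=acmg,
        vus_subclass=subclass,
        ppot=ppot if ppot is not None and ppot.met else None,
        reportable=reportable,
        evidence=evidence,
    )
    return evidence, verdict


def builtin_cases() -> tuple[FixtureCase, ...]:
    """The four curated worked examples."""
    cases: list[FixtureCase] = []

    # --- SERPINA6 missense: PP3/BP4 both inapplicable, BP1 via missense-Z ---
    serpina6 = VariantAnnotation(
        sample_id="CASE_SERPINA6",
        gene=GENES["SERPINA6"],
        transcript="NM_001756.4",
        hgvs_c="c.1165G>A",
        hgvs_p="p.(Asp389Asn)",
        consequence=ConsequenceClass.MISSENSE,
        zygosity="het",
        scores=PredictorScores(revel=0.518, cadd_phred=24.78, rank_scores=make_rank_scores(11)),
        population=PopulationData(gnomad_hom_count=0, coverage_ok=True),
        clinvar=ClinVarSummary(classification="VUS", stars=2, n_submissions=5),
        upstream_calls=(
            _upstream("PM2", "Supporting", "GnomAD genomes homozygous allele count = 0"),
            _upstream("BP4", "Strong", "MetaRNN = 0.0134 is between 0.00692 and 0.108"),
            _upstream("BP1", "Supporting", "GnomAD missense Z-score is -0.662"),
            _upstream(
                "PP5",
                "Supporting",
                "ClinVar classifies this variant as Uncertain Significance, 2 stars",
            ),
        ),
    )
    evidence, verdict = _expected(
        [
            _call(Criterion.BP1, StrengthLevel.BP),
            _call(Criterion.PM2, StrengthLevel.PM),
            _call(Criterion.PP5, StrengthLevel.PP),
        ],
        AcmgClass.VUS,
        VusSubclass.MIDDLE,
        reportable=False,
    )
    cases.append(
        FixtureCase(
            name="SERPINA6",
            annotation=serpina6,
            config=FIXTURE_CONFIG,
            expected_evidence=evidence,
            expected_verdict=verdict,
            citation="worked example 1: BP1+PM2+PP5 -> VUS Middle",
        )
    )

    # --- TYR frameshift: graded PVS1 via the no-NMD, <10%-removed branch ---
    tyr = VariantAnnotation(
        sample_id="CASE_TYR",
        gene=GENES["TYR"],
        transcript="NM_000372.5",
        hgvs_c="c.1586del",
        hgvs_p="p.(Leu529Tyrfs*7)",
        consequence=ConsequenceClass.FRAMESHIFT,
        zygosity="het",
        lof=LoFAnnotation(
            lof_type="frameshift",
            nmd_predicted=False,
            exon_in_relevant_transcript=True,
            lof_frequent_in_population=False,
            fraction_protein_removed=0.0019,
            truncated_region_critical=False,
            pathogenic_variants_in_truncated_region=0,
        ),
        population=PopulationData(gnomad_allele_count=0, coverage_ok=True),
        upstream_calls=(_upstream("PM2", "Supporting", "Variant not found in gnomAD genomes"),),
    )
    evidence, verdict = _expected(
        [
            _call(Criterion.PVS1, StrengthLevel.PM),
            _call(Criterion.PM2, StrengthLevel.PM),
        ],
        AcmgClass.VUS,
        VusSubclass.MIDDLE,
        reportable=False,
    )
    cases.append(
        FixtureCase(
            name="TYR",
            annotation=tyr,
            config=FIXTURE_CONFIG,
            expected_evidence=evidence,
            expected_verdict=verdict,
            citation="worked example 2: PVS1(Moderate, NP6)+PM2 -> VUS Middle",
        )
    )

    # --- USH2A missense with pathogenic partner: P_POT via in-trans chance ---
    ush2a = VariantAnnotation(
        sample_id="CASE_USH2A",
        gene=GENES["USH2A"],
        transcript="NM_206933.4",
        hgvs_c="c.5213T>C",
        hgvs_p="p.(Phe1738Ser)",
        consequence=ConsequenceClass.MISSENSE,
        zygosity="het",
        scores=PredictorScores(revel=0.767, cadd_phred=28.30, rank_scores=make_rank_scores(14)),
        population=PopulationData(gnomad_allele_count=0, coverage_ok=True),
        upstream_calls=(
            _upstream("PM2", "Supporting", "Variant not found in gnomAD genomes"),
            _upstream("PP4", "Supporting", "clinical diagnosis of Usher syndrome (case specific)"),
        ),
    )
    ush2a_partner = VariantAnnotation(
        sample_id="CASE_USH2A",
        gene=GENES["USH2A"],
        transcript="NM_206933.4",
        hgvs_c="c.2299del",
        hgvs_p="p.(Glu767Serfs*21)",
        consequence=ConsequenceClass.FRAMESHIFT,
        zygosity="het",
        lof=LoFAnnotation(
            lof_type="frameshift",
            nmd_predicted=True,
            exon_in_relevant_transcript=True,
            lof_frequent_in_population=False,
            fraction_protein_removed=0.85,
        ),
        population=PopulationData(coverage_ok=True),
        clinvar=ClinVarSummary(classification="P", stars=3, n_submissions=20),
        upstream_calls=(
            _upstream("PM2", "Supporting"),
            _upstream("PP5", "Supporting", "ClinVar classifies this variant as Pathogenic"),
        ),
    )
    evidence, verdict = _expected(
        [
            _call(Criterion.PP3, StrengthLevel.PP),
            _call(Criterion.BP1, StrengthLevel.BP),
            _call(Criterion.PM2, StrengthLevel.PM),
            _call(Criterion.PP4, StrengthLevel.PP),
            _call(
                Criterion.PPOT,
                StrengthLevel.PP,
                rationale="possible in-trans configuration with the pathogenic "
                "USH2A:NM_206933.4:c.2299del variant",
            ),
        ],
        AcmgClass.VUS,
        VusSubclass.HOT,
        reportable=True,
    )
    cases.append(
        FixtureCase(
            name="USH2A",
            annotation=ush2a,
            context_annotations=(ush2a_partner,),
            config=FIXTURE_CONFIG,
            expected_evidence=evidence,
            expected_verdict=verdict,
            citation="worked example 3: PP3+BP1+PM2+PP4+P_POT(Supporting) -> VUS Hot",
        )
    )

    # --- CELSR1 missense in an AD gene: P_POT via possible de novo ---
    celsr1 = VariantAnnotation(
        sample_id="CASE_CELSR1",
        gene=GENES["CELSR1"],
        transcript="NM_014246.4",
        hgvs_c="c.5165G>A",
        hgvs_p="p.(Arg1722Gln)",
        consequence=ConsequenceClass.MISSENSE,
        zygosity="het",
        scores=PredictorScores(revel=0.723, cadd_phred=29.1, rank_scores=make_rank_scores(13)),
        population=PopulationData(gnomad_allele_count=2, coverage_ok=True),
        upstream_calls=(
            _upstream("PM2", "Supporting", "GnomAD genomes allele count = 2 is less than 5"),
        ),
    )
    evidence, verdict = _expected(
        [
            _call(Criterion.PP3, StrengthLevel.PP),
            _call(Criterion.BP1, StrengthLevel.BP),
            _call(Criterion.PM2, StrengthLevel.PM),
            _call(Criterion.PPOT, StrengthLevel.PM, rationale="possible de novo variant"),
        ],
        AcmgClass.VUS,
        VusSubclass.HOT,
        reportable=True,
    )
    cases.append(
        FixtureCase(
            name="CELSR1",
            annotation=celsr1,
            config=FIXTURE_CONFIG,
            expected_evidence=evidence,
            expected_verdict=verdict,
            citation="worked example 4: PP3+BP1+PM2+P_POT(Moderate) -> VUS Hot",
        )
    )
    return tuple(cases)


def run_case(case: FixtureCase) -> Verdict:
    """Run one fixture end-to-end (criteria -> combiner -> P_POT) and return
    the verdict of the case's primary variant."""
    from .pipeline import classify_annotation
    from .ppot import apply_ppot
    from .model import ClassifiedVariant

    variants = []
    for annotation in (case.annotation,) + case.context_annotations:
        verdict = classify_annotation(annotation, case.config)
        variants.append(ClassifiedVariant(annotation=annotation, verdict=verdict))
    ctx = apply_ppot(
        SampleContext(sample_id=case.annotation.sample_id, variants=tuple(variants))
    )
    for entry in ctx.variants:
        if entry.annotation.hgvs_c == case.annotation.hgvs_c:
            return entry.verdict
    raise AssertionError("case variant lost during classification")


# ---------------------------------------------------------------------------
# synthetic generator

Profile = Literal["missense", "splice", "lof", "mixed"]


def _missense_templates(cfg: ThresholdConfig, rng: random.Random):
    yield {  # all three pathogenic conditions
        "consequence": ConsequenceClass.MISSENSE,
        "scores": PredictorScores(
            revel=rng.uniform(cfg.revel_path, 1.0),
            cadd_phred=rng.uniform(cfg.cadd_path, 40.0),
            rank_scores=make_rank_scores(rng.randint(8, 15)),
        ),
    }
    yield {  # all three benign conditions
        "consequence": ConsequenceClass.MISSENSE,
        "scores": PredictorScores(
            revel=rng.uniform(0.0, cfg.revel_benign),
            cadd_phred=rng.uniform(0.0, cfg.cadd_benign),
            rank_scores=make_rank_scores(0, benign=rng.uniform(0.0, cfg.rank_cutoff_benign)),
        ),
    }
    yield {  # intermediate scores: neither rule
        "consequence": ConsequenceClass.MISSENSE,
        "scores": PredictorScores(
            revel=rng.uniform(cfg.revel_benign + 0.01, cfg.revel_path - 0.01),
            cadd_phred=rng.uniform(cfg.cadd_benign + 0.1, cfg.cadd_path - 0.1),
            rank_scores=make_rank_scores(rng.randint(0, 7), damaging=0.70, benign=0.45),
        ),
    }
    yield {  # boundary: scores exactly at the pathogenic cutoffs (inclusive)
        "consequence": ConsequenceClass.MISSENSE,
        "scores": PredictorScores(
            revel=cfg.revel_path,
            cadd_phred=cfg.cadd_path,
            rank_scores={name: cfg.rank_cutoff_path for name in RANK_PREDICTORS},
        ),
    }
    yield {  # missense+splice, missense conditions evaluable
        "consequence": ConsequenceClass.MISSENSE_SPLICE,
        "scores": PredictorScores(
            revel=rng.uniform(cfg.revel_path, 1.0),
            cadd_phred=rng.uniform(cfg.cadd_path, 40.0),
            rank_scores=make_rank_scores(12),
            ada_boost=rng.random(),
            rf=rng.random(),
        ),
    }
    yield {  # missense+splice fallback: missense inputs missing
        "consequence": ConsequenceClass.MISSENSE_SPLICE,
        "scores": PredictorScores(
            ada_boost=rng.uniform(cfg.ada_cutoff, 1.0), rf=rng.uniform(cfg.rf_cutoff, 1.0)
        ),
    }


def _splice_templates(cfg: ThresholdConfig, rng: random.Random):
    for consequence in (
        ConsequenceClass.SYNONYMOUS_SPLICE,
        ConsequenceClass.SPLICE_REGION,
        ConsequenceClass.INTRONIC_WITHIN_5,
    ):
        yield {  # pathogenic splice rule
            "consequence": consequence,
            "scores": PredictorScores(
                ada_boost=rng.uniform(cfg.ada_cutoff, 1.0), rf=rng.uniform(cfg.rf_cutoff, 1.0)
            ),
        }
        yield {  # benign splice rule
            "consequence": consequence,
            "scores": PredictorScores(
                ada_boost=rng.uniform(0.0, cfg.ada_cutoff), rf=rng.uniform(0.0, cfg.rf_cutoff)
            ),
        }
    yield {  # exact boundary: both splice rules fire -> conflict, neither
        "consequence": ConsequenceClass.SPLICE_REGION,
        "scores": PredictorScores(ada_boost=cfg.ada_cutoff, rf=cfg.rf_cutoff),
    }


def _lof_templates(cfg: ThresholdConfig, rng: random.Random):
    def lof(consequence: ConsequenceClass, **kw):
        base = dict(
            nmd_predicted=False,
            exon_in_relevant_transcript=True,
            lof_frequent_in_population=False,
            fraction_protein_removed=rng.random(),
        )
        base.update(kw)
        return {"consequence": consequence, "lof": LoFAnnotation(**base)}

    fs = ConsequenceClass.FRAMESHIFT
    ns = ConsequenceClass.NONSENSE
    yield lof(fs, lof_type="frameshift", nmd_predicted=True)  # NP1
    yield lof(ns, lof_type="nonsense", nmd_predicted=True, exon_in_relevant_transcript=False)  # NP2
    yield lof(fs, lof_type="frameshift", truncated_region_critical=True)  # NP3
    yield lof(ns, lof_type="nonsense", lof_frequent_in_population=True)  # NP4
    yield lof(fs, lof_type="frameshift", fraction_protein_removed=rng.uniform(0.10, 1.0))  # NP5
    yield lof(fs, lof_type="frameshift", fraction_protein_removed=rng.uniform(0.0, 0.099))  # NP6
    cs = ConsequenceClass.CANONICAL_SPLICE
    yield lof(cs, lof_type="canonical_splice", nmd_predicted=True, splice_rescue_possible=False)
    yield lof(cs, lof_type="canonical_splice", splice_rescue_possible=False,
              fraction_protein_removed=rng.uniform(0.10, 1.0))
    yield lof(cs, lof_type="canonical_splice", splice_rescue_possible=True,
              fraction_protein_removed=rng.uniform(0.0, 0.099))
    yield lof(cs, lof_type="canonical_splice", splice_rescue_possible=True,
              truncated_region_critical=True)
    sl = ConsequenceClass.START_LOSS
    yield lof(sl, lof_type="start_loss", pathogenic_variants_in_truncated_region=rng.randint(1, 9))
    yield lof(sl, lof_type="start_loss", pathogenic_variants_in_truncated_region=0)


_ZYGOSITY_FOR = {"AD": "het", "AR": "hom", "XL": "hemi"}


def generate_annotations(
    seed: int, n: int, profile: Profile = "mixed"
) -> list[VariantAnnotation]:
    """Generate ``n`` reproducible, valid variant records covering every
    PP3/BP4 branch (including cutoff boundaries), every PVS1 tree branch and
    every inheritance/zygosity pairing relevant to P_POT."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = random.Random(seed)
    makers = {
        "missense": (_missense_templates,),
        "splice": (_splice_templates,),
        "lof": (_lof_templates,),
        "mixed": (_missense_templates, _splice_templates, _lof_templates),
    }[profile]

    inheritance_cycle = itertools.cycle(["AD", "AR", "XL"])
    out: list[VariantAnnotation] = []
    template_pool: list[dict] = []
    while len(template_pool) < n:
        for maker in makers:
            template_pool.extend(maker(FIXTURE_CONFIG, rng))
    for i in range(n):
        template = template_pool[i]
        mode = next(inheritance_cycle)
        consequence = template["consequence"]
        is_lof = "lof" in template
        gene = GeneInfo(
            symbol=f"GENE{i % 17:03d}",
            inheritance=frozenset({mode}),
            benign_nonvus_missense=rng.randint(0, 50),
            total_nonvus_missense=rng.randint(50, 600),
            lof_mechanism=True if is_lof else None,
        )
        zygosity = _ZYGOSITY_FOR[mode] if rng.random() < 0.5 else "het"
        if zygosity == "hemi" and mode != "XL":
            zygosity = "het"
        out.append(
            VariantAnnotation(
                sample_id=f"SYN{i:04d}",
                gene=gene,
                transcript=f"NM_{100000 + i}.1",
                hgvs_c=f"c.{100 + i}A>G" if not is_lof else f"c.{100 + i}del",
                consequence=consequence,
                zygosity=zygosity,
                scores=template.get("scores", PredictorScores()),
                population=PopulationData(
                    maf_by_source={"gnomAD": rng.uniform(0.0, 0.05)}
                    if rng.random() < 0.3
                    else {},
                    coverage_ok=True,
                ),
                lof=template.get("lof"),
            )
        )
    return out


def enumerate_counts(limits: StrengthCounts | tuple[int, ...]) -> Iterator[StrengthCounts]:
    """Full Cartesian enumeration of strength tallies up to per-bucket maxima."""
    limits = StrengthCounts(*limits)
    for combo in itertools.product(*(range(v + 1) for v in limits)):
        yield StrengthCounts(*combo)
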