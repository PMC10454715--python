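import random

import pytest

from acmgvus.criteria import (
    assign_bp1,
    assign_bp4,
    assign_criteria,
    assign_pp3,
    benign_fraction_pct,
    count_rank_scores,
    decision_maf,
    modify_bp6,
    modify_pm2,
)
from acmgvus.model import (
    ConsequenceClass,
    Criterion,
    GeneInfo,
    PopulationData,
    PredictorScores,
    RANK_PREDICTORS,
    StrengthLevel,
    ThresholdConfig,
)
from acmgvus.fixtures import make_rank_scores


def scores(revel=None, cadd=None, n_damaging=None, ada=None, rf=None, **kw):
    rank = make_rank_scores(n_damaging, **kw) if n_damaging is not None else {}
    return PredictorScores(revel=revel, cadd_phred=cadd, rank_scores=rank, ada_boost=ada, rf=rf)


class TestCountRankScores:
    def test_14_of_15_damaging(self, cfg):
        assert count_rank_scores(make_and(14), 0.644, "ge") == (14, 15)

    def test_all_missing(self):
        assert count_rank_scores(PredictorScores(), 0.644, "ge") == (0, 0)

    def test_boundary_inclusive(self):
        s = PredictorScores(rank_scores={n: 0.644 for n in RANK_PREDICTORS})
        assert count_rank_scores(s, 0.644, "ge") == (15, 15)
        assert count_rank_scores(s, 0.644, "le") == (15, 15)


def make_and(n):
    return PredictorScores(rank_scores=make_rank_scores(n))


class TestAssignPp3Missense:
    def test_three_of_three(self, cfg):
        d = assign_pp3(ConsequenceClass.MISSENSE, scores(0.767, 28.30, 14), cfg)
        assert d.verdict == "pp3_met" and d.branch == "missense"
        assert sum(d.conditions_met[k] for k in ("revel", "cadd", "rank_majority")) == 3

    def test_one_of_three_not_met(self, cfg):
        d = assign_pp3(ConsequenceClass.MISSENSE, scores(0.518, 24.78, 11), cfg)
        assert d.verdict == "neither"

    def test_two_of_three_met(self, cfg):
        d = assign_pp3(ConsequenceClass.MISSENSE, scores(0.723, 29.1, 13), cfg)
        assert d.verdict == "pp3_met"
        d = assign_pp3(ConsequenceClass.MISSENSE, scores(0.7, 20.0, 13), cfg)
        assert d.verdict == "pp3_met"  # revel + ranks, CADD below

    def test_boundary_equality_counts(self, cfg):
        d = assign_pp3(ConsequenceClass.MISSENSE, scores(0.644, 25.3, 0), cfg)
        assert d.verdict == "pp3_met"

    def test_nonqualifying_consequence(self, cfg):
        d = assign_pp3(ConsequenceClass.OTHER, scores(0.9, 30, 15), cfg)
        assert d.verdict == "not_applicable"


class TestAssignPp3Splice:
    @pytest.mark.parametrize(
        "consequence",
        [
            ConsequenceClass.SYNONYMOUS_SPLICE,
            ConsequenceClass.SPLICE_REGION,
            ConsequenceClass.INTRONIC_WITHIN_5,
        ],
    )
    def test_splice_rule(self, cfg, consequence):
        assert assign_pp3(consequence, scores(ada=0.9, rf=0.6), cfg).verdict == "pp3_met"
        assert assign_pp3(consequence, scores(ada=0.9, rf=0.4), cfg).verdict == "neither"
        assert assign_pp3(consequence, scores(ada=0.5, rf=0.6), cfg).verdict == "neither"

    def test_missense_splice_uses_missense_when_evaluable(self, cfg):
        # 2/3 missense conditions available and satisfied; splice scores benign
        d = assign_pp3(ConsequenceClass.MISSENSE_SPLICE, scores(0.7, 30.0, ada=0.1, rf=0.1), cfg)
        assert d.verdict == "pp3_met" and d.branch == "missense"

    def test_missense_splice_fallback_when_not_applicable(self, cfg):
        # only REVEL present -> fewer than 2 evaluable -> splice fallback
        d = assign_pp3(ConsequenceClass.MISSENSE_SPLICE, scores(revel=0.9, ada=0.9, rf=0.6), cfg)
        assert d.verdict == "pp3_met" and d.branch == "missense_fallback_splice"


class TestAssignBp4:
    def test_zero_of_three_benign(self, cfg):
        d = assign_bp4(ConsequenceClass.MISSENSE, scores(0.518, 24.78, 11), cfg)
        assert d.verdict == "neither"

    def test_three_of_three_benign(self, cfg):
        s = scores(0.05, 3.0, 0, benign=0.1)
        d = assign_bp4(ConsequenceClass.MISSENSE, s, cfg)
        assert d.verdict == "bp4_met"

    def test_splice_boundary_conflict(self, cfg):
        s = scores(ada=0.708, rf=0.515)
        pp3 = assign_pp3(ConsequenceClass.SPLICE_REGION, s, cfg)
        bp4 = assign_bp4(ConsequenceClass.SPLICE_REGION, s, cfg)
        assert pp3.verdict == "neither" and bp4.verdict == "neither"
        assert "conflict" in pp3.rationale and "conflict" in bp4.rationale


SEEDED_N = 2000


class TestPp3Bp4Properties:
    @pytest.mark.parametrize(
        "consequence",
        [
            ConsequenceClass.MISSENSE,
            ConsequenceClass.MISSENSE_SPLICE,
            ConsequenceClass.SYNONYMOUS_SPLICE,
            ConsequenceClass.SPLICE_REGION,
            ConsequenceClass.INTRONIC_WITHIN_5,
        ],
    )
    def test_never_both_met(self, cfg, consequence):
        rng = random.Random(20240101)
        for _ in range(SEEDED_N):
            s = _random_scores(rng)
            pp3 = assign_pp3(consequence, s, cfg)
            bp4 = assign_bp4(consequence, s, cfg)
            assert not (pp3.verdict == "pp3_met" and bp4.verdict == "bp4_met")

    def test_monotone(self, cfg):
        rng = random.Random(4242)
        for _ in range(500):
            s = _random_scores(rng)
            raised = _shift_scores(s, rng, up=True)
            lowered = _shift_scores(s, rng, up=False)
            for consequence in (ConsequenceClass.MISSENSE, ConsequenceClass.SPLICE_REGION):
                if assign_pp3(consequence, s, cfg).verdict == "pp3_met":
                    assert assign_pp3(consequence, raised, cfg).verdict == "pp3_met"
                if assign_bp4(consequence, s, cfg).verdict == "bp4_met":
                    assert assign_bp4(consequence, lowered, cfg).verdict == "bp4_met"


def _random_scores(rng):
    return PredictorScores(
        revel=rng.random() if rng.random() < 0.9 else None,
        cadd_phred=rng.uniform(0, 40) if rng.random() < 0.9 else None,
        rank_scores={n: rng.random() for n in RANK_PREDICTORS if rng.random() < 0.8},
        ada_boost=round(rng.random(), 3) if rng.random() < 0.9 else None,
        rf=round(rng.random(), 3) if rng.random() < 0.9 else None,
    )


def _shift_scores(s, rng, up):
    def move(v, hi):
        if v is None:
            return None
        delta = rng.random() * (hi - v) if up else -rng.random() * v
        return min(hi, max(0.0, v + delta))

    return PredictorScores(
        revel=move(s.revel, 1.0),
        cadd_phred=move(s.cadd_phred, 40.0),
        rank_scores={k: move(v, 1.0) for k, v in s.rank_scores.items()},
        ada_boost=move(s.ada_boost, 1.0),
        rf=move(s.rf, 1.0),
    )


class TestModifyPm2:
    def test_supporting_reassigned_moderate(self):
        c = modify_pm2(True, StrengthLevel.PP)
        assert c.met and c.strength is StrengthLevel.PM

    def test_strong_reassigned_moderate(self):
        assert modify_pm2(True, StrengthLevel.PS).strength is StrengthLevel.PM

    def test_moderate_identity(self):
        assert modify_pm2(True, StrengthLevel.PM).strength is StrengthLevel.PM

    def test_not_triggered(self):
        assert not modify_pm2(False).met


class TestModifyBp6:
    def test_very_strong_downgraded(self):
        c = modify_bp6(True, "VeryStrong")
        assert c.met and c.strength is StrengthLevel.BP and c.source == "auto"

    def test_moderate_downgraded(self):
        assert modify_bp6(True, "Moderate").strength is StrengthLevel.BP

    def test_strong_passes_through(self):
        c = modify_bp6(True, "Strong")
        assert c.strength is StrengthLevel.BS

    def test_supporting_passes_through(self):
        assert modify_bp6(True, "Supporting").strength is StrengthLevel.BP

    def test_not_triggered(self):
        assert not modify_bp6(False).met


class TestAssignBp1:
    def test_benign_fraction_ush2a(self, cfg):
        gene = GeneInfo(symbol="USH2A", benign_nonvus_missense=196, total_nonvus_missense=529)
        c = assign_bp1(gene, ConsequenceClass.MISSENSE, cfg)
        assert c.met and c.strength is StrengthLevel.BP
        assert "37.1%" in c.rationale

    def test_benign_fraction_celsr1(self, cfg):
        gene = GeneInfo(symbol="CELSR1", benign_nonvus_missense=33, total_nonvus_missense=33)
        c = assign_bp1(gene, ConsequenceClass.MISSENSE, cfg)
        assert c.met and "100.0%" in c.rationale

    def test_zero_benign_not_met(self, cfg):
        gene = GeneInfo(symbol="G", benign_nonvus_missense=0, total_nonvus_missense=529)
        assert not assign_bp1(gene, ConsequenceClass.MISSENSE, cfg).met

    def test_z_rule_default_off(self, cfg):
        gene = GeneInfo(symbol="SERPINA6", missense_z=-0.662)
        assert not assign_bp1(gene, ConsequenceClass.MISSENSE, cfg).met

    def test_z_rule_per_gene_opt_in(self):
        cfg = ThresholdConfig(bp1_missense_z_genes=("SERPINA6",))
        gene = GeneInfo(symbol="SERPINA6", missense_z=-0.662)
        c = assign_bp1(gene, ConsequenceClass.MISSENSE, cfg)
        assert c.met and "-0.662" in c.rationale

    def test_non_missense_never_met(self, cfg):
        gene = GeneInfo(symbol="G", benign_nonvus_missense=50, total_nonvus_missense=50)
        assert not assign_bp1(gene, ConsequenceClass.FRAMESHIFT, cfg).met

    def test_rounding_half_away_from_zero(self):
        assert benign_fraction_pct(196, 529) == 37.1
        assert benign_fraction_pct(33, 33) == 100.0
        assert benign_fraction_pct(1, 8) == 12.5
        assert benign_fraction_pct(5, 8) == 62.5
        assert benign_fraction_pct(1, 16) == 6.3  # 6.25 rounds away from zero


class TestDecisionMaf:
    def test_above_threshold_fails(self, cfg):
        maf, ok = decision_maf(PopulationData(maf_by_source={"gnomAD": 0.05}), cfg)
        assert (maf, ok) == (0.05, False)

    def test_absent_passes(self, cfg):
        assert decision_maf(PopulationData(), cfg) == (0.0, True)

    def test_maximum_integration(self, cfg):
        pop = PopulationData(maf_by_source={"dbNSFP": 0.001, "VEP": 0.002, "gnomAD": 0.0})
        assert decision_maf(pop, cfg) == (0.002, True)

    def test_exact_threshold_fails(self, cfg):
        _, ok = decision_maf(PopulationData(maf_by_source={"gnomAD": 0.03}), cfg)
        assert not ok

    def test_monotone_in_each_source(self, cfg):
        rng = random.Random(9)
        for _ in range(200):
            f = {k: rng.random() * 0.06 for k in ("dbNSFP", "VEP", "gnomAD")}
            maf1, _ = decision_maf(PopulationData(maf_by_source=f), cfg)
            src = rng.choice(list(f))
            f2 = dict(f)
            f2[src] = min(1.0, f[src] + rng.random() * 0.05)
            maf2, _ = decision_maf(PopulationData(maf_by_source=f2), cfg)
            assert maf2 >= maf1


class TestAssignCriteria:
    def test_serpina6_record(self, cases):
        case = cases["SERPINA6"]
        ev = assign_criteria(case.annotation, case.config)
        met = {(c.criterion, c.strength) for c in ev.met_calls}
        assert met == {
            (Criterion.BP1, StrengthLevel.BP),
            (Criterion.PM2, StrengthLevel.PM),
            (Criterion.PP5, StrengthLevel.PP),
        }
        bp4 = ev.get(Criterion.BP4)
        assert bp4 is not None and not bp4.met  # upstream Strong overridden

    def test_tyr_record(self, cases):
        case = cases["TYR"]
        ev = assign_criteria(case.annotation, case.config)
        met = {(c.criterion, c.strength) for c in ev.met_calls}
        assert met == {
            (Criterion.PVS1, StrengthLevel.PM),
            (Criterion.PM2, StrengthLevel.PM),
        }

    def test_bare_absent_variant_gets_pm2_only(self, cfg):
        from acmgvus.model import VariantAnnotation

        variant = VariantAnnotation(
            sample_id="S",
            gene=GeneInfo(symbol="G"),
            transcript="NM_1.1",
            hgvs_c="c.1A>G",
            consequence=ConsequenceClass.MISSENSE,
            zygosity="het",
        )
        ev = assign_criteria(variant, cfg)
        assert {c.criterion for c in ev.met_calls} == {Criterion.PM2}

    def test_pp5_capped_at_supporting(self, cfg):
        from acmgvus.model import EvidenceCall, VariantAnnotation

        variant = VariantAnnotation(
            sample_id="S",
            gene=GeneInfo(symbol="G"),
            transcript="NM_1.1",
            hgvs_c="c.1A>G",
            consequence=ConsequenceClass.MISSENSE,
            zygosity="het",
            upstream_calls=(
                EvidenceCall(
                    criterion=Criterion.PP5,
                    met=True,
                    strength=StrengthLevel.PS,
                    source="upstream",
                ),
            ),
        )
        ev = assign_criteria(variant, cfg)
        assert ev.get(Criterion.PP5).strength is StrengthLevel.PP

    def test_duplicate_upstream_rejected(self, cfg):
        from pydantic import ValidationError

        from acmgvus.model import EvidenceCall, VariantAnnotation

        with pytest.raises(ValidationError):
            VariantAnnotation(
                sample_id="S",
                gene=GeneInfo(symbol="G"),
                transcript="NM_1.1",
                hgvs_c="c.1A>G",
                consequence=ConsequenceClass.MISSENSE,
                zygosity="het",
                upstream_calls=(
                    EvidenceCall(criterion=Criterion.PP4, met=True, strength=StrengthLevel.PP),
                    EvidenceCall(criterion=Criterion.PP4, met=False),
                ),
            )
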