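"""Domain types shared by every stage of the classification engine.

The model is deliberately flat: a variant record carries everything the
rule engine needs (scores, frequencies, gene statistics, a structured
loss-of-function block), criteria are represented as :class:`EvidenceCall`
objects carrying an *effective* strength, and the combiner consumes only
the tally of met calls per strength bucket (:class:`StrengthCounts`).
"""

from __future__ import annotations

import enum
import json
from pathlib import Path
from typing import Literal, NamedTuple, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_serializer, model_validator

__all__ = [
    "Polarity",
    "StrengthLevel",
    "Criterion",
    "EvidenceCall",
    "EvidenceSet",
    "StrengthCounts",
    "effective_counts",
    "PredictorScores",
    "RANK_PREDICTORS",
    "ThresholdConfig",
    "ConsequenceClass",
    "LOF_CONSEQUENCES",
    "PopulationData",
    "GeneInfo",
    "LoFAnnotation",
    "ClinVarSummary",
    "VariantAnnotation",
    "AcmgClass",
    "VusSubclass",
    "Verdict",
    "ClassifiedVariant",
    "SampleContext",
    "parse_strength",
]


class Polarity(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class StrengthLevel(str, enum.Enum):
    """Effective evidence strength, named by its ACMG bucket code.

    Pathogenic buckets: PVS > PS > PM > PP.
    Benign buckets: BA (stand-alone) > BS > BP.
    """

    PVS = "PVS"
    PS = "PS"
    PM = "PM"
    PP = "PP"
    BA = "BA"
    BS = "BS"
    BP = "BP"

    @property
    def polarity(self) -> Polarity:
        return Polarity.BENIGN if self.value.startswith("B") else Polarity.PATHOGENIC

    @property
    def rank(self) -> int:
        """Order within a polarity (higher = stronger)."""
        return _STRENGTH_RANK[self]

    @property
    def label(self) -> str:
        """Human-readable strength name."""
        return _STRENGTH_LABEL[self]


_STRENGTH_RANK = {
    StrengthLevel.PVS: 4,
    StrengthLevel.PS: 3,
    StrengthLevel.PM: 2,
    StrengthLevel.PP: 1,
    StrengthLevel.BA: 3,
    StrengthLevel.BS: 2,
    StrengthLevel.BP: 1,
}

_STRENGTH_LABEL = {
    StrengthLevel.PVS: "VeryStrong",
    StrengthLevel.PS: "Strong",
    StrengthLevel.PM: "Moderate",
    StrengthLevel.PP: "Supporting",
    StrengthLevel.BA: "StandAlone",
    StrengthLevel.BS: "Strong",
    StrengthLevel.BP: "Supporting",
}


def parse_strength(label: str, polarity: Polarity) -> StrengthLevel:
    """Map a strength label ("Moderate", "very_strong", "PM", ...) onto the
    bucket enum, resolving polarity-ambiguous labels (Strong, Supporting).

    Raises ``ValueError`` for labels illegal under the given polarity
    (e.g. Moderate on the benign side).
    """
    norm = label.strip().replace("_", "").replace(" ", "").replace("-", "").lower()
    by_code = {s.value.lower(): s for s in StrengthLevel}
    if norm in by_code:
        lvl = by_code[norm]
        if lvl.polarity is not polarity:
            raise ValueError(f"strength {label!r} has wrong polarity for {polarity.value}")
        return lvl
    table = {
        (Polarity.PATHOGENIC, "verystrong"): StrengthLevel.PVS,
        (Polarity.PATHOGENIC, "strong"): StrengthLevel.PS,
        (Polarity.PATHOGENIC, "moderate"): StrengthLevel.PM,
        (Polarity.PATHOGENIC, "supporting"): StrengthLevel.PP,
        (Polarity.BENIGN, "standalone"): StrengthLevel.BA,
        (Polarity.BENIGN, "strong"): StrengthLevel.BS,
        (Polarity.BENIGN, "supporting"): StrengthLevel.BP,
    }
    try:
        return table[(polarity, norm)]
    except KeyError:
        raise ValueError(f"strength {label!r} is not valid for polarity {polarity.value}") from None


class Criterion(str, enum.Enum):
    """The 28 ACMG/AMP evidence criteria plus the pathogenicity-potential proxy."""

    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PS3 = "PS3"
    PS4 = "PS4"
    PM1 = "PM1"
    PM2 = "PM2"
    PM3 = "PM3"
    PM4 = "PM4"
    PM5 = "PM5"
    PM6 = "PM6"
    PP1 = "PP1"
    PP2 = "PP2"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"
    BA1 = "BA1"
    BS1 = "BS1"
    BS2 = "BS2"
    BS3 = "BS3"
    BS4 = "BS4"
    BP1 = "BP1"
    BP2 = "BP2"
    BP3 = "BP3"
    BP4 = "BP4"
    BP5 = "BP5"
    BP6 = "BP6"
    BP7 = "BP7"
    PPOT = "P_POT"

    @property
    def polarity(self) -> Polarity:
        return Polarity.BENIGN if self.value.startswith("B") else Polarity.PATHOGENIC

    @property
    def default_strength(self) -> StrengthLevel:
        if self is Criterion.PPOT:
            return StrengthLevel.PM
        return StrengthLevel(self.value[:-1] if self.value[-1].isdigit() else self.value)


class EvidenceCall(BaseModel):
    """One criterion decision with its effective strength and provenance."""

    model_config = ConfigDict(frozen=True)

    criterion: Criterion
    met: bool
    strength: Optional[StrengthLevel] = None
    rationale: str = ""
    source: Literal["auto", "upstream", "user"] = "auto"

    @model_validator(mode="after")
    def _check(self) -> "EvidenceCall":
        if not self.met:
            if self.strength is not None:
                raise ValueError(f"{self.criterion.value}: strength given but criterion not met")
            return self
        if self.strength is None:
            raise ValueError(f"{self.criterion.value}: met call requires a strength")
        if self.strength.polarity is not self.criterion.polarity:
            raise ValueError(
                f"{self.criterion.value}: strength {self.strength.value} has wrong polarity"
            )
        return self


class EvidenceSet(BaseModel):
    """The per-variant checklist: at most one call per criterion."""

    model_config = ConfigDict(frozen=True)

    calls: tuple[EvidenceCall, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "EvidenceSet":
        seen = set()
        for call in self.calls:
            if call.criterion in seen:
                raise ValueError(f"duplicate call for {call.criterion.value}")
            seen.add(call.criterion)
        for a, b in ((Criterion.PP3, Criterion.BP4), (Criterion.PP5, Criterion.BP6)):
            if self.is_met(a) and self.is_met(b):
                raise ValueError(f"{a.value} and {b.value} cannot both be met")
        return self

    def get(self, criterion: Criterion) -> Optional[EvidenceCall]:
        for call in self.calls:
            if call.criterion is criterion:
                return call
        return None

    def is_met(self, criterion: Criterion) -> bool:
        call = self.get(criterion)
        return call is not None and call.met

    @property
    def met_calls(self) -> tuple[EvidenceCall, ...]:
        return tuple(c for c in self.calls if c.met)

    def with_call(self, call: EvidenceCall) -> "EvidenceSet":
        """Return a copy with ``call`` added, replacing any same-criterion call."""
        kept = tuple(c for c in self.calls if c.criterion is not call.criterion)
        return EvidenceSet(calls=kept + (call,))

    def without(self, criterion: Criterion) -> "EvidenceSet":
        return EvidenceSet(calls=tuple(c for c in self.calls if c.criterion is not criterion))


class StrengthCounts(NamedTuple):
    """Tally of met evidence at effective strengths — the combiner's sole input."""

    pvs: int = 0
    ps: int = 0
    pm: int = 0
    pp: int = 0
    ba: int = 0
    bs: int = 0
    bp: int = 0

    @property
    def n_pathogenic(self) -> int:
        return self.pvs + self.ps + self.pm + self.pp

    @property
    def n_benign(self) -> int:
        return self.ba + self.bs + self.bp


_BUCKET_FIELD = {
    StrengthLevel.PVS: "pvs",
    StrengthLevel.PS: "ps",
    StrengthLevel.PM: "pm",
    StrengthLevel.PP: "pp",
    StrengthLevel.BA: "ba",
    StrengthLevel.BS: "bs",
    StrengthLevel.BP: "bp",
}


def effective_counts(evidence: EvidenceSet, include_ppot: bool = False) -> StrengthCounts:
    """Tally met calls at their effective strengths.

    A criterion carried at a non-default strength (e.g. PVS1 at Moderate)
    counts in the bucket of its *effective* strength. The P_POT call is
    included only when ``include_ppot`` is true.
    """
    tally = dict.fromkeys(_BUCKET_FIELD.values(), 0)
    for call in evidence.calls:
        if not call.met:
            continue
        if call.criterion is Criterion.PPOT and not include_ppot:
            continue
        tally[_BUCKET_FIELD[call.strength]] += 1
    return StrengthCounts(**tally)


RANK_PREDICTORS: tuple[str, ...] = (
    "DANN",
    "EigenPC",
    "FATHMM",
    "LRT",
    "MCAP",
    "MetaLR",
    "MetaSVM",
    "MutPred",
    "MutationAssessor",
    "MutationTaster",
    "PROVEAN",
    "Polyphen2HDIV",
    "Polyphen2HVAR",
    "SIFT",
    "VEST3",
)


class PredictorScores(BaseModel):
    """In-silico predictor scores; every entry is optional."""

    model_config = ConfigDict(frozen=True)

    revel: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    cadd_phred: Optional[float] = Field(default=None, ge=0.0)
    rank_scores: dict[str, float] = Field(default_factory=dict)
    ada_boost: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    rf: Optional[float] = Field(default=None, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "PredictorScores":
        bad = set(self.rank_scores) - set(RANK_PREDICTORS)
        if bad:
            raise ValueError(f"unknown rank-score predictors: {sorted(bad)}")
        for name, value in self.rank_scores.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"rank score {name}={value} outside [0, 1]")
        return self


class ThresholdConfig(BaseModel):
    """Every numeric cutoff used by the rule engine, with published defaults."""

    model_config = ConfigDict(frozen=True)

    revel_path: float = 0.644
    revel_benign: float = 0.29
    cadd_path: float = 25.3
    cadd_benign: float = 22.7
    rank_cutoff_path: float = 0.644
    rank_cutoff_benign: float = 0.29
    n_rank_required: int = 8
    n_rank_total: int = 15
    ada_cutoff: float = 0.708
    rf_cutoff: float = 0.515
    bp1_benign_fraction_pct: float = 33.1
    bp1_missense_z: float = 2.99
    decision_maf_pct: float = 3.0
    # The missense-Z sub-rule of BP1 fires for almost any gene, so it is
    # opt-in per gene symbol rather than global.
    bp1_missense_z_genes: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "ThresholdConfig":
        numeric = (
            self.revel_path,
            self.revel_benign,
            self.cadd_path,
            self.cadd_benign,
            self.rank_cutoff_path,
            self.rank_cutoff_benign,
            self.ada_cutoff,
            self.rf_cutoff,
            self.bp1_benign_fraction_pct,
            self.bp1_missense_z,
            self.decision_maf_pct,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all threshold values must be positive")
        if self.revel_benign >= self.revel_path:
            raise ValueError("REVEL benign cutoff must be below the pathogenic cutoff")
        if self.cadd_benign >= self.cadd_path:
            raise ValueError("CADD benign cutoff must be below the pathogenic cutoff")
        return self

    @classmethod
    def load(cls, path: str | Path) -> "ThresholdConfig":
        """Load thresholds from a YAML or JSON file; missing keys keep defaults."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if data is None:
            data = {}
        if "bp1_missense_z_genes" in data:
            data["bp1_missense_z_genes"] = tuple(data["bp1_missense_z_genes"])
        return cls(**data)


class ConsequenceClass(str, enum.Enum):
    MISSENSE = "missense"
    MISSENSE_SPLICE = "missense_splice"
    SYNONYMOUS_SPLICE = "synonymous_splice"
    SPLICE_REGION = "splice_region"
    INTRONIC_WITHIN_5 = "intronic_within_5"
    FRAMESHIFT = "frameshift"
    NONSENSE = "nonsense"
    CANONICAL_SPLICE = "canonical_splice"
    START_LOSS = "start_loss"
    OTHER = "other"


#: Consequence classes that require a structured LoF annotation block.
LOF_CONSEQUENCES = frozenset(
    {
        ConsequenceClass.FRAMESHIFT,
        ConsequenceClass.NONSENSE,
        ConsequenceClass.CANONICAL_SPLICE,
        ConsequenceClass.START_LOSS,
    }
)


class PopulationData(BaseModel):
    model_config = ConfigDict(frozen=True)

    maf_by_source: dict[Literal["dbNSFP", "VEP", "gnomAD"], float] = Field(default_factory=dict)
    gnomad_allele_count: Optional[int] = Field(default=None, ge=0)
    gnomad_hom_count: Optional[int] = Field(default=None, ge=0)
    coverage_ok: Optional[bool] = None

    @model_validator(mode="after")
    def _check(self) -> "PopulationData":
        for src, freq in self.maf_by_source.items():
            if not 0.0 <= freq <= 1.0:
                raise ValueError(f"frequency for {src} outside [0, 1]")
        return self


class GeneInfo(BaseModel):
    model_config = ConfigDict(frozen=True)

    symbol: str
    inheritance: frozenset[Literal["AD", "AR", "XL"]] = frozenset()
    missense_z: Optional[float] = None
    benign_nonvus_missense: Optional[int] = Field(default=None, ge=0)
    total_nonvus_missense: Optional[int] = Field(default=None, ge=0)
    lof_mechanism: Optional[bool] = None

    @field_serializer("inheritance")
    def _serialize_inheritance(self, value: frozenset) -> list[str]:
        # sorted so JSON output is byte-stable across hash-randomized runs
        return sorted(value)

    @model_validator(mode="after")
    def _check(self) -> "GeneInfo":
        if (
            self.benign_nonvus_missense is not None
            and self.total_nonvus_missense is not None
            and self.benign_nonvus_missense > self.total_nonvus_missense
        ):
            raise ValueError("benign non-VUS missense count exceeds total")
        return self


class LoFAnnotation(BaseModel):
    """Pre-computed facts feeding the PVS1 decision tree."""

    model_config = ConfigDict(frozen=True)

    lof_type: Literal["frameshift", "nonsense", "canonical_splice", "start_loss", "exon_deletion"]
    nmd_predicted: bool
    exon_in_relevant_transcript: bool
    lof_frequent_in_population: bool
    fraction_protein_removed: float = Field(ge=0.0, le=1.0)
    truncated_region_critical: Optional[bool] = None
    pathogenic_variants_in_truncated_region: Optional[int] = Field(default=None, ge=0)
    splice_rescue_possible: Optional[bool] = None


class ClinVarSummary(BaseModel):
    model_config = ConfigDict(frozen=True)

    classification: Literal["P", "LP", "VUS", "LB", "B", "conflicting", "none"] = "none"
    stars: int = Field(default=0, ge=0, le=4)
    n_submissions: int = Field(default=0, ge=0)


class VariantAnnotation(BaseModel):
    """All upstream facts about one variant observed in one sample."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    gene: GeneInfo
    transcript: str
    hgvs_c: str
    hgvs_p: Optional[str] = None
    consequence: ConsequenceClass
    zygosity: Literal["het", "hom", "hemi"]
    scores: PredictorScores = Field(default_factory=PredictorScores)
    population: PopulationData = Field(default_factory=PopulationData)
    lof: Optional[LoFAnnotation] = None
    clinvar: Optional[ClinVarSummary] = None
    upstream_calls: tuple[EvidenceCall, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "VariantAnnotation":
        if not self.hgvs_c:
            raise ValueError("hgvs_c must be non-empty")
        is_lof = self.consequence in LOF_CONSEQUENCES
        if is_lof and self.lof is None:
            raise ValueError(f"{self.consequence.value} variant requires a lof block")
        if not is_lof and self.lof is not None:
            raise ValueError(f"{self.consequence.value} variant must not carry a lof block")
        seen = set()
        for call in self.upstream_calls:
            if call.criterion in seen:
                raise ValueError(f"duplicate upstream call for {call.criterion.value}")
            seen.add(call.criterion)
        return self

    @property
    def annotation(self) -> str:
        return f"{self.gene.symbol}:{self.transcript}:{self.hgvs_c}"


class AcmgClass(str, enum.Enum):
    B = "B"
    LB = "LB"
    VUS = "VUS"
    LP = "LP"
    P = "P"
    FILTERED = "filtered"


class VusSubclass(str, enum.Enum):
    HOT = "Hot"
    MIDDLE = "Middle"
    COLD = "Cold"
    NONE = "none"


_SUBCLASS_ORDER = {VusSubclass.COLD: 0, VusSubclass.MIDDLE: 1, VusSubclass.HOT: 2}


class Verdict(BaseModel):
    model_config = ConfigDict(frozen=True)

    acmg_class: AcmgClass
    vus_subclass: VusSubclass = VusSubclass.NONE
    ppot: Optional[EvidenceCall] = None
    reportable: bool
    evidence: EvidenceSet = Field(default_factory=EvidenceSet)
    explanation: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "Verdict":
        is_vus = self.acmg_class is AcmgClass.VUS
        if is_vus != (self.vus_subclass is not VusSubclass.NONE):
            raise ValueError("vus_subclass must be set exactly when acmg_class is VUS")
        if self.ppot is not None and not is_vus:
            raise ValueError("P_POT may only be attached to a VUS verdict")
        expected = self.acmg_class in (AcmgClass.P, AcmgClass.LP) or (
            is_vus and self.vus_subclass is VusSubclass.HOT
        )
        if self.reportable != expected:
            raise ValueError("reportable flag inconsistent with class/subclass")
        return self


class ClassifiedVariant(BaseModel):
    model_config = ConfigDict(frozen=True)

    annotation: VariantAnnotation
    verdict: Verdict


class SampleContext(BaseModel):
    """All classified variants of one individual, the unit P_POT logic works on."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    variants: tuple[ClassifiedVariant, ...] = ()

    @model_validator(mode="after")
    def _check(self) -> "SampleContext":
        for entry in self.variants:
            if entry.annotation.sample_id != self.sample_id:
                raise ValueError("all variants in a SampleContext must share its sample_id")
        return self

    def by_gene(self, symbol: str) -> tuple[ClassifiedVariant, ...]:
        return tuple(v for v in self.variants if v.annotation.gene.symbol == symbol)
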