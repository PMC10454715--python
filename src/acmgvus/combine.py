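"""Evidence combination: ACMG 2015 class plus Hot/Middle/Cold VUS lookup.

The subclass mapping is shipped as a TSV (one row per strength pattern) so
it can be audited row by row; the loader verifies that no pattern repeats
and that every row is genuinely VUS under the combining rules.
"""

from __future__ import annotations

import csv
import logging
from functools import lru_cache
from importlib import resources
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .model import (
    AcmgClass,
    Criterion,
    EvidenceSet,
    StrengthCounts,
    Verdict,
    VusSubclass,
    effective_counts,
)

logger = logging.getLogger(__name__)


def acmg_verdict(counts: StrengthCounts) -> AcmgClass:
    """Apply the ACMG 2015 combining rules to a strength tally.

    The tally must exclude P_POT. A simultaneous pathogenic-side and
    benign-side match, or no match at all, yields VUS.
    """
    pvs, ps, pm, pp, ba, bs, bp = counts

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs == 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp == 1) or bp >= 2

    path_side = pathogenic or likely_pathogenic
    benign_side = benign or likely_benign
    if path_side and benign_side:
        return AcmgClass.VUS
    if pathogenic:
        return AcmgClass.P
    if likely_pathogenic:
        return AcmgClass.LP
    if benign:
        return AcmgClass.B
    if likely_benign:
        return AcmgClass.LB
    return AcmgClass.VUS


class SubclassTable(BaseModel):
    """The printed Hot/Middle/Cold pattern table (36 rows)."""

    model_config = ConfigDict(frozen=True)

    rows: tuple[tuple[StrengthCounts, VusSubclass], ...]

    @property
    def mapping(self) -> dict[StrengthCounts, VusSubclass]:
        return dict(self.rows)

    def validate_rows(self) -> None:
        seen: dict[StrengthCounts, VusSubclass] = {}
        for pattern, subclass in self.rows:
            if pattern in seen:
                raise ValueError(f"duplicate pattern {pattern}")
            seen[pattern] = subclass
            if acmg_verdict(pattern) is not AcmgClass.VUS:
                raise ValueError(
                    f"pattern {pattern} is {acmg_verdict(pattern).value}, not VUS"
                )


@lru_cache(maxsize=1)
def load_subclass_table() -> SubclassTable:
    """Load and validate the shipped subclass TSV."""
    text = resources.files("acmgvus.data").joinpath("subclass_table.tsv").read_text()
    rows = []
    for rec in csv.DictReader(text.splitlines(), delimiter="\t"):
        pattern = StrengthCounts(
            *(int(rec[k]) for k in ("pvs", "ps", "pm", "pp", "ba", "bs", "bp"))
        )
        rows.append((pattern, VusSubclass(rec["subclass"])))
    table = SubclassTable(rows=tuple(rows))
    table.validate_rows()
    return table


class SubclassResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    subclass: VusSubclass
    fallback: bool = False
    matched_pattern: Optional[StrengthCounts] = None
    note: str = ""


def _fallback_sequence(counts: StrengthCounts):
    """Deterministic reduction order for patterns outside the printed table:
    drop benign evidence one call at a time (BP, then BS, then BA), then drop
    the weakest pathogenic evidence (PP, then PM, PS, PVS)."""
    current = counts
    for field in ("bp", "bs", "ba"):
        while getattr(current, field) > 0:
            current = current._replace(**{field: getattr(current, field) - 1})
            yield current
    for field in ("pp", "pm", "ps", "pvs"):
        while getattr(current, field) > 0:
            current = current._replace(**{field: getattr(current, field) - 1})
            yield current


def vus_subclass(counts: StrengthCounts) -> SubclassResult:
    """Exact pattern lookup with a deterministic fallback for unprinted
    combinations (always flagged); defaults to Middle when nothing matches."""
    mapping = load_subclass_table().mapping
    if counts in mapping:
        return SubclassResult(subclass=mapping[counts], matched_pattern=counts)
    for reduced in _fallback_sequence(counts):
        if reduced in mapping:
            logger.info("fallback: pattern %s reduced to %s", counts, reduced)
            return SubclassResult(
                subclass=mapping[reduced],
                fallback=True,
                matched_pattern=reduced,
                note=f"fallback: pattern {tuple(counts)} not in table, reduced to {tuple(reduced)}",
            )
    logger.info("fallback: pattern %s has no reduction; defaulting to Middle", counts)
    return SubclassResult(
        subclass=VusSubclass.MIDDLE,
        fallback=True,
        note=f"fallback: pattern {tuple(counts)} not reducible to any table row; Middle by default",
    )


def classify_variant(evidence: EvidenceSet) -> Verdict:
    """ACMG class from the P_POT-free tally; for VUS, subclass from the tally
    including P_POT when a met P_POT call is present."""
    counts = effective_counts(evidence, include_ppot=False)
    acmg = acmg_verdict(counts)

    explanation = [
        f"{call.criterion.value} {call.strength.label}: {call.rationale}".rstrip(": ")
        for call in evidence.met_calls
    ]
    explanation.append(f"ACMG class: {acmg.value}")

    ppot_call = evidence.get(Criterion.PPOT)
    if ppot_call is not None and not ppot_call.met:
        ppot_call = None

    subclass = VusSubclass.NONE
    if acmg is AcmgClass.VUS:
        sub_counts = effective_counts(evidence, include_ppot=True) if ppot_call else counts
        result = vus_subclass(sub_counts)
        subclass = result.subclass
        if result.fallback:
            explanation.append(result.note)
        explanation.append(f"VUS subclass: {subclass.value}")

    reportable = acmg in (AcmgClass.P, AcmgClass.LP) or subclass is VusSubclass.HOT
    return Verdict(
        acmg_class=acmg,
        vus_subclass=subclass,
        ppot=ppot_call if acmg is AcmgClass.VUS else None,
        reportable=reportable,
        evidence=evidence,
        explanation=tuple(explanation),
    )
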