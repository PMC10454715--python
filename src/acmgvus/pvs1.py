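"""Graded PVS1 assignment from a structured loss-of-function annotation.

The decision tree consumes pre-computed facts (NMD prediction, exon
relevance, population frequency of LoF, fraction of protein removed)
instead of raw transcript structure; each outcome carries a path code so
the route through the tree is auditable.

Path code prefixes: NP (nonsense/frameshift), DEL (whole-exon deletion),
SS (canonical splice), IC (initiation codon / start loss).
"""

from __future__ import annotations

import logging
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .model import GeneInfo, LoFAnnotation, StrengthLevel

logger = logging.getLogger(__name__)

#: Truncations removing at least this fraction of the protein stay Strong
#: on the no-NMD branch; smaller truncations drop to Moderate.
PROTEIN_FRACTION_CUTOFF = 0.10


class Pvs1Result(BaseModel):
    model_config = ConfigDict(frozen=True)

    met: bool
    strength: Optional[StrengthLevel] = None
    path_code: str = ""
    rationale: str = ""


def _result(met: bool, strength: Optional[StrengthLevel], code: str, rationale: str) -> Pvs1Result:
    return Pvs1Result(met=met, strength=strength, path_code=code, rationale=rationale)


def _truncating_branch(lof: LoFAnnotation, prefix: str) -> Pvs1Result:
    """Shared tree for frameshift, nonsense and whole-exon deletions."""
    if lof.nmd_predicted:
        if lof.exon_in_relevant_transcript:
            return _result(
                True,
                StrengthLevel.PVS,
                f"{prefix}1",
                f"{prefix}1—Predicted to undergo NMD and exon is present in "
                "biologically relevant transcript(s)",
            )
        return _result(
            False,
            None,
            f"{prefix}2",
            f"{prefix}2—Predicted to undergo NMD but exon is absent from "
            "biologically relevant transcripts",
        )
    if lof.truncated_region_critical:
        return _result(
            True,
            StrengthLevel.PS,
            f"{prefix}3",
            f"{prefix}3—Not predicted to undergo NMD and truncated/altered "
            "region is critical to protein function",
        )
    if lof.lof_frequent_in_population or not lof.exon_in_relevant_transcript:
        return _result(
            False,
            None,
            f"{prefix}4",
            f"{prefix}4—LoF variants in this exon are frequent in the general "
            "population and/or exon is absent from biologically relevant transcripts",
        )
    common = (
        f"LoF variants in this exon are not frequent in the general population "
        f"and exon is present in biologically relevant transcript(s)"
    )
    if lof.fraction_protein_removed >= PROTEIN_FRACTION_CUTOFF:
        return _result(
            True,
            StrengthLevel.PS,
            f"{prefix}5",
            f"{prefix}5—{common}—Variants remove >10% of protein",
        )
    return _result(
        True,
        StrengthLevel.PM,
        f"{prefix}6",
        f"{prefix}6—{common}—Variants remove <10% of protein",
    )


def _splice_branch(lof: LoFAnnotation) -> Pvs1Result:
    if lof.lof_frequent_in_population or not lof.exon_in_relevant_transcript:
        return _result(
            False,
            None,
            "SS4",
            "SS4—LoF variants in this exon are frequent in the general population "
            "and/or exon is absent from biologically relevant transcripts",
        )
    if not lof.splice_rescue_possible:
        # Disruptive splice change: same grading as a direct truncation.
        if lof.nmd_predicted:
            return _result(
                True,
                StrengthLevel.PVS,
                "SS1",
                "SS1—Exon skipping or cryptic splice site disrupts reading frame "
                "and is predicted to undergo NMD",
            )
        if lof.truncated_region_critical:
            return _result(
                True,
                StrengthLevel.PS,
                "SS3",
                "SS3—Disrupted region is critical to protein function",
            )
        if lof.fraction_protein_removed >= PROTEIN_FRACTION_CUTOFF:
            return _result(
                True,
                StrengthLevel.PS,
                "SS5",
                "SS5—Frame-disrupting splice change removes >10% of protein",
            )
        return _result(
            True,
            StrengthLevel.PM,
            "SS6",
            "SS6—Frame-disrupting splice change removes <10% of protein",
        )
    # In-frame rescue (exon skipping / cryptic site preserving reading frame):
    # one strength level below the disruptive outcomes.
    if lof.truncated_region_critical:
        return _result(
            True,
            StrengthLevel.PS,
            "SS7",
            "SS7—In-frame rescue but altered region is critical to protein function",
        )
    if lof.fraction_protein_removed >= PROTEIN_FRACTION_CUTOFF:
        return _result(
            True,
            StrengthLevel.PM,
            "SS8",
            "SS8—In-frame rescue removing >10% of protein",
        )
    return _result(
        True,
        StrengthLevel.PP,
        "SS9",
        "SS9—In-frame rescue removing <10% of protein",
    )


def _start_loss_branch(lof: LoFAnnotation) -> Pvs1Result:
    n_path = lof.pathogenic_variants_in_truncated_region or 0
    if n_path > 0:
        return _result(
            True,
            StrengthLevel.PM,
            "IC1",
            f"IC1—{n_path} pathogenic variant(s) upstream of the closest "
            "potential in-frame start codon",
        )
    return _result(
        True,
        StrengthLevel.PP,
        "IC3",
        "IC3—No pathogenic variants upstream of the closest potential "
        "in-frame start codon",
    )


_BRANCHES = {
    "frameshift": lambda lof: _truncating_branch(lof, "NP"),
    "nonsense": lambda lof: _truncating_branch(lof, "NP"),
    "exon_deletion": lambda lof: _truncating_branch(lof, "DEL"),
    "canonical_splice": _splice_branch,
    "start_loss": _start_loss_branch,
}


def classify_pvs1(lof: LoFAnnotation, gene: GeneInfo) -> Pvs1Result:
    """Walk the PVS1 decision tree for one loss-of-function variant.

    Requires ``gene.lof_mechanism`` to be known; genes where loss of
    function is not an established disease mechanism never receive PVS1.
    """
    if lof is None:
        raise ValueError("classify_pvs1 requires a LoF annotation block")
    if gene.lof_mechanism is None:
        raise ValueError(f"lof_mechanism unknown for gene {gene.symbol}")
    if not gene.lof_mechanism:
        return _result(
            False,
            None,
            "MECH0",
            f"Loss of function is not a known disease mechanism for gene {gene.symbol}",
        )
    branch = _BRANCHES.get(lof.lof_type)
    if branch is None:  # pragma: no cover - enum already restricts lof_type
        logger.warning("unknown lof_type %r; PVS1 not assigned", lof.lof_type)
        return _result(False, None, "UNK0", f"Unknown LoF type {lof.lof_type!r}")
    return branch(lof)
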