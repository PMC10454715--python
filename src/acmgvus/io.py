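"""Readers and writers: input records, gene table, segregation results,
threshold config and the classification report.

JSON Lines is the canonical rich input format (one object per variant per
sample, mapping 1:1 onto :class:`~acmgvus.model.VariantAnnotation`); the
three-column CSV (SAMPLEID, PANEL_NAME, ANNOTATION) is accepted for
bare annotations without structured blocks.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Any, Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .criteria import modify_bp6
from .model import (
    ClinVarSummary,
    ConsequenceClass,
    Criterion,
    EvidenceCall,
    GeneInfo,
    LoFAnnotation,
    PopulationData,
    PredictorScores,
    SampleContext,
    StrengthLevel,
    VariantAnnotation,
    parse_strength,
)
from .ppot import SegregationResult

_NM_RE = re.compile(r"^NM_\d+(\.\d+)?$")


class RecordError(BaseModel):
    model_config = ConfigDict(frozen=True)

    line: int
    message: str


class InputRecord(BaseModel):
    """One uploaded variant line plus its optional structured blocks."""

    model_config = ConfigDict(frozen=True)

    sample_id: str
    panel: str = ""
    annotation: str
    hgvs_p: Optional[str] = None
    consequence: str = "other"
    zygosity: Literal["het", "hom", "hemi"] = "het"
    scores: dict[str, Any] = Field(default_factory=dict)
    population: dict[str, Any] = Field(default_factory=dict)
    lof: Optional[dict[str, Any]] = None
    clinvar: Optional[dict[str, Any]] = None
    upstream_calls: tuple[dict[str, Any], ...] = ()
    gene: Optional[dict[str, Any]] = None

    @model_validator(mode="after")
    def _check(self) -> "InputRecord":
        parts = self.annotation.split(":")
        if len(parts) != 3 or not all(parts):
            raise ValueError(
                f"annotation {self.annotation!r} must be GENE:NM_accession:c-change"
            )
        if not _NM_RE.match(parts[1]):
            raise ValueError(f"{parts[1]!r} is not an NM_ accession")
        return self

    @property
    def gene_symbol(self) -> str:
        return self.annotation.split(":")[0]

    def to_annotation(self, gene_table: dict[str, GeneInfo]) -> VariantAnnotation:
        symbol, transcript, hgvs_c = self.annotation.split(":")
        gene = (
            GeneInfo(**self.gene)
            if self.gene is not None
            else gene_table.get(symbol, GeneInfo(symbol=symbol))
        )
        return VariantAnnotation(
            sample_id=self.sample_id,
            gene=gene,
            transcript=transcript,
            hgvs_c=hgvs_c,
            hgvs_p=self.hgvs_p,
            consequence=ConsequenceClass(self.consequence),
            zygosity=self.zygosity,
            scores=PredictorScores(**self.scores),
            population=PopulationData(**self.population),
            lof=LoFAnnotation(**self.lof) if self.lof is not None else None,
            clinvar=ClinVarSummary(**self.clinvar) if self.clinvar is not None else None,
            upstream_calls=tuple(parse_upstream_call(c) for c in self.upstream_calls),
        )


def parse_upstream_call(raw: dict[str, Any]) -> EvidenceCall:
    """Build an upstream EvidenceCall from a raw dict; strength may be a
    bucket code ("PM") or a label ("Moderate").

    A BP6 call at a level outside the benign lattice (Very Strong,
    Moderate) is normalized through the BP6 strength-modification rule.
    """
    criterion = Criterion(raw["criterion"])
    met = bool(raw.get("met", True))
    label = raw.get("strength")
    if not met:
        return EvidenceCall(
            criterion=criterion, met=False, rationale=raw.get("rationale", ""), source="upstream"
        )
    if criterion is Criterion.BP6:
        call = modify_bp6(True, label)
        if raw.get("rationale"):
            call = call.model_copy(update={"rationale": raw["rationale"]})
        return call
    strength = (
        parse_strength(str(label), criterion.polarity)
        if label is not None
        else criterion.default_strength
    )
    return EvidenceCall(
        criterion=criterion,
        met=True,
        strength=strength,
        rationale=raw.get("rationale", ""),
        source=raw.get("source", "upstream"),
    )


def read_records(
    path: str | Path, format: Literal["jsonl", "csv"] = "jsonl"
) -> tuple[list[InputRecord], list[RecordError]]:
    """Parse an input file; malformed rows are collected, valid rows proceed."""
    path = Path(path)
    records: list[InputRecord] = []
    errors: list[RecordError] = []
    if format == "jsonl":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            try:
                records.append(InputRecord(**json.loads(line)))
            except Exception as exc:  # noqa: BLE001 - collect every parse failure
                errors.append(RecordError(line=lineno, message=str(exc)))
    elif format == "csv":
        with path.open(newline="") as handle:
            for lineno, row in enumerate(csv.reader(handle), start=1):
                if not row or all(not cell.strip() for cell in row):
                    continue
                if lineno == 1 and [c.strip().upper() for c in row[:3]] == [
                    "SAMPLEID",
                    "PANEL_NAME",
                    "ANNOTATION",
                ]:
                    continue  # optional header
                if len(row) < 3:
                    errors.append(
                        RecordError(line=lineno, message=f"expected 3 columns, got {len(row)}")
                    )
                    continue
                try:
                    records.append(
                        InputRecord(
                            sample_id=row[0].strip(),
                            panel=row[1].strip(),
                            annotation=row[2].strip(),
                        )
                    )
                except Exception as exc:  # noqa: BLE001
                    errors.append(RecordError(line=lineno, message=str(exc)))
    else:
        raise ValueError(f"unknown format {format!r}")
    return records, errors


def read_gene_table(path: str | Path) -> dict[str, GeneInfo]:
    """Gene-info TSV: symbol, inheritance, missense_z, benign_nonvus_missense,
    total_nonvus_missense, lof_mechanism. Inheritance modes are separated by
    "," or "/"; empty cells mean unknown."""
    genes: dict[str, GeneInfo] = {}
    with Path(path).open(newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            inheritance = frozenset(
                m.strip() for m in re.split(r"[,/]", row.get("inheritance") or "") if m.strip()
            )
            def _num(key: str, cast):
                value = (row.get(key) or "").strip()
                return cast(value) if value else None

            lof_raw = (row.get("lof_mechanism") or "").strip().lower()
            genes[row["symbol"]] = GeneInfo(
                symbol=row["symbol"],
                inheritance=inheritance,
                missense_z=_num("missense_z", float),
                benign_nonvus_missense=_num("benign_nonvus_missense", int),
                total_nonvus_missense=_num("total_nonvus_missense", int),
                lof_mechanism=None if not lof_raw else lof_raw in ("true", "1", "yes"),
            )
    return genes


def read_segregation(path: str | Path) -> dict[tuple[str, str, str], SegregationResult]:
    """Segregation TSV keyed by (sample_id, gene, hgvs_c)."""
    results: dict[tuple[str, str, str], SegregationResult] = {}
    with Path(path).open(newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            key = (row["sample_id"], row["gene"], row["hgvs_c"])
            meioses = (row.get("meioses") or "").strip()
            results[key] = SegregationResult(
                kind=row["kind"],
                meioses=int(meioses) if meioses else None,
                parentage_confirmed=(row.get("parentage_confirmed") or "").strip().lower()
                in ("true", "1", "yes"),
                observed_in_healthy=(row.get("observed_in_healthy") or "").strip().lower()
                in ("true", "1", "yes"),
            )
    return results


def read_edits(path: str | Path) -> dict[tuple[str, str], list[dict[str, Any]]]:
    """User confirmation TSV (sample_id, hgvs_c, criterion, met, strength)
    keyed by (sample_id, hgvs_c)."""
    edits: dict[tuple[str, str], list[dict[str, Any]]] = {}
    with Path(path).open(newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            edits.setdefault((row["sample_id"], row["hgvs_c"]), []).append(
                {
                    "criterion": row["criterion"],
                    "met": (row.get("met") or "true").strip().lower() in ("true", "1", "yes"),
                    "strength": (row.get("strength") or "").strip() or None,
                }
            )
    return edits


def _render_text(contexts: list[SampleContext]) -> str:
    lines: list[str] = []
    for ctx in contexts:
        lines.append(f"Sample {ctx.sample_id}")
        lines.append("=" * (7 + len(ctx.sample_id)))
        for entry in ctx.variants:
            ann, verdict = entry.annotation, entry.verdict
            lines.append(f"\n{ann.annotation}" + (f" {ann.hgvs_p}" if ann.hgvs_p else ""))
            for call in verdict.evidence.calls:
                status = (
                    f"{call.strength.label}: {call.rationale}"
                    if call.met
                    else f"Not applicable: {call.rationale}".rstrip(": ")
                )
                lines.append(f"  {call.criterion.value:<6} {status}")
            final = verdict.acmg_class.value
            if verdict.vus_subclass.value != "none":
                final += f" {verdict.vus_subclass.value}"
                if verdict.ppot is not None:
                    final += " (potential)"
            lines.append(f"  Final  {final}  reportable={str(verdict.reportable).lower()}")
            if ann.scores.rank_scores:
                listed = ", ".join(f"{k}={v:g}" for k, v in sorted(ann.scores.rank_scores.items()))
                lines.append(f"  Predictors: {listed}")
        lines.append("")
    return "\n".join(lines)


def _render_tsv(contexts: list[SampleContext]) -> str:
    header = [
        "sample_id",
        "gene",
        "annotation",
        "acmg_class",
        "vus_subclass",
        "reportable",
        "met_criteria",
    ]
    rows = ["\t".join(header)]
    for ctx in contexts:
        for entry in ctx.variants:
            met = ";".join(
                f"{c.criterion.value}@{c.strength.label}" for c in entry.verdict.evidence.met_calls
            )
            rows.append(
                "\t".join(
                    [
                        ctx.sample_id,
                        entry.annotation.gene.symbol,
                        entry.annotation.annotation,
                        entry.verdict.acmg_class.value,
                        entry.verdict.vus_subclass.value,
                        str(entry.verdict.reportable).lower(),
                        met,
                    ]
                )
            )
    return "\n".join(rows) + "\n"


def write_report(
    contexts: list[SampleContext],
    path: str | Path,
    format: Literal["json", "tsv", "text"] = "json",
) -> None:
    """Write the classification report; the JSON form round-trips through
    :func:`read_report`."""
    path = Path(path)
    if format == "json":
        payload = {"samples": [ctx.model_dump(mode="json") for ctx in contexts]}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        path.write_text(_render_tsv(contexts))
    elif format == "text":
        path.write_text(_render_text(contexts) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[SampleContext]:
    payload = json.loads(Path(path).read_text())
    return [SampleContext.model_validate(item) for item in payload["samples"]]
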