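# acmgvus

A rule engine for germline variant classification: it assigns and
strength-modifies ACMG/AMP evidence criteria from structured annotation
records, combines them into the 2015 five-tier verdict, subclassifies
variants of uncertain significance (VUS) into **Hot / Middle / Cold**, and
applies a sample-aware *pathogenicity potential* proxy criterion (`P_POT`)
to decide which VUS belong in a diagnostic report. Only Pathogenic, Likely
Pathogenic and Hot VUS are reportable.

## What it does

1. **Pre-filter** — a decision minor-allele frequency (maximum over the
   dbNSFP / VEP / gnomAD entries) must be below 3%, otherwise the variant
   is filtered before classification.
2. **Criterion assignment** (`acmgvus.criteria`)
   - `PP3` / `BP4` from in-silico predictors, per consequence class:
     missense variants need at least 2/3 of {REVEL ≥ 0.644, CADD ≥ 25.3,
     ≥ 8/15 predictor rank scores ≥ 0.644} (benign mirror: ≤ 0.29 / ≤ 22.7
     / ≤ 0.29); splice-affecting classes use AdaBoost ≥ 0.708 AND RF ≥
     0.515 (benign mirror with ≤).
   - `PM2` re-assigned to Moderate whenever triggered; `BP6` triggered at
     Very Strong or Moderate is re-assigned Supporting (a geneticist may
     later confirm/upgrade via the `confirm` subcommand).
   - `BP1` for missense variants when the benign fraction of non-VUS
     missense variants in the gene exceeds 33.1% (a per-gene opt-in
     missense-Z sub-rule, z < 2.99, is also available).
   - `PVS1` via a graded decision tree (`acmgvus.pvs1`) over a structured
     loss-of-function block (NMD prediction, exon relevance, fraction of
     protein removed, …), yielding VeryStrong → Supporting with auditable
     path codes (e.g. `NP6` = no NMD, relevant exon, < 10% of protein
     removed → Moderate).
   - Upstream-attributed criteria (PS1, PM1, PP4, …) pass through
     verbatim; engine-owned criteria override upstream calls.
3. **Combination** (`acmgvus.combine`) — the 2015 combining rules produce
   B / LB / VUS / LP / P; VUS are then matched exactly against the shipped
   36-row strength-pattern table (`src/acmgvus/data/subclass_table.tsv`,
   16 Hot / 10 Middle / 10 Cold rows) with a deterministic, always-flagged
   fallback for unprinted patterns.
4. **P_POT** (`acmgvus.ppot`) — Middle VUS receive the proxy criterion at
   Moderate (downgraded to Supporting for the 1 PM + 2 PP and 2 PM
   combinations) when segregation testing could upgrade them: another
   P/LP/Hot/Middle variant in the same recessive gene, homozygous in a
   recessive gene, heterozygous in a dominant gene, or hemizygous in an
   X-linked gene. Promoted variants become Hot (potential) and reportable.
   Once real segregation results arrive, `resolve_segregation` swaps
   P_POT for the established criterion (PS2/PM6, PM3, PP1 — or BS4, BP2,
   BS2 when refuted) and reclassifies.

## CLI

```bash
# classify a record file (JSON Lines; or CSV "SAMPLEID,PANEL_NAME,ANNOTATION")
acmgvus classify --in variants.jsonl --genes genes.tsv \
    --config thresholds.yaml --out report.json
acmgvus classify --in variants.jsonl --genes genes.tsv --out report.txt --out-format text

# verbose per-criterion trace for one variant
acmgvus explain --in variants.jsonl --genes genes.tsv \
    --annotation "TYR:NM_000372.5:c.1586del"

# check the shipped Hot/Middle/Cold table invariants
acmgvus validate-table

# apply user strength confirmations (e.g. BP6 Supporting -> Strong) and re-emit
acmgvus confirm --in variants.jsonl --edits edits.tsv --out report.json

# write the builtin worked-example fixtures, or synthetic records
acmgvus fixtures --out-dir tests/data
acmgvus fixtures --out-dir scratch/ --generate 200 --seed 7 --profile mixed
```

Input formats are plain text: JSON Lines for fully structured records
(scores, population data, LoF block, upstream calls), a gene-info TSV
(`symbol`, `inheritance`, `missense_z`, `benign_nonvus_missense`,
`total_nonvus_missense`, `lof_mechanism`), an optional YAML/JSON threshold
config, and optional segregation / edits TSVs. See
`tests/data/builtin.jsonl` for a complete example.

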