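{"annotation": "SERPINA6:NM_001756.4:c.1165G>A", "clinvar": {"classification": "VUS", "n_submissions": 5, "stars": 2}, "consequence": "missense", "hgvs_p": "p.(Asp389Asn)", "lof": null, "panel": "FIXTURE", "population": {"coverage_ok": true, "gnomad_hom_count": 0, "maf_by_source": {}}, "sample_id": "CASE_SERPINA6", "scores": {"cadd_phred": 24.78, "rank_scores": {"DANN": 0.75, "EigenPC": 0.75, "FATHMM": 0.75, "LRT": 0.75, "MCAP": 0.75, "MetaLR": 0.75, "MetaSVM": 0.75, "MutPred": 0.75, "MutationAssessor": 0.75, "MutationTaster": 0.75, "PROVEAN": 0.75, "Polyphen2HDIV": 0.2, "Polyphen2HVAR": 0.2, "SIFT": 0.2, "VEST3": 0.2}, "revel": 0.518}, "upstream_calls": [{"criterion": "PM2", "met": true, "rationale": "GnomAD genomes homozygous allele count = 0", "strength": "Supporting"}, {"criterion": "BP4", "met": true, "rationale": "MetaRNN = 0.0134 is between 0.00692 and 0.108", "strength": "Strong"}, {"criterion": "BP1", "met": true, "rationale": "GnomAD missense Z-score is -0.662", "strength": "Supporting"}, {"criterion": "PP5", "met": true, "rationale": "ClinVar classifies this variant as Uncertain Significance, 2 stars", "strength": "Supporting"}], "zygosity": "het"}
{"annotation": "TYR:NM_000372.5:c.1586del", "clinvar": null, "consequence": "frameshift", "hgvs_p": "p.(Leu529Tyrfs*7)", "lof": {"exon_in_relevant_transcript": true, "fraction_protein_removed": 0.0019, "lof_frequent_in_population": false, "lof_type": "frameshift", "nmd_predicted": false, "pathogenic_variants_in_truncated_region": 0, "splice_rescue_possible": null, "truncated_region_critical": false}, "panel": "FIXTURE", "population": {"coverage_ok": true, "gnomad_allele_count": 0, "maf_by_source": {}}, "sample_id": "CASE_TYR", "scores": {"rank_scores": {}}, "upstream_calls": [{"criterion": "PM2", "met": true, "rationale": "Variant not found in gnomAD genomes", "strength": "Supporting"}], "zygosity": "het"}
{"annotation": "USH2A:NM_206933.4:c.5213T>C", "clinvar": null, "consequence": "missense", "hgvs_p": "p.(Phe1738Ser)", "lof": null, "panel": "FIXTURE", "population": {"coverage_ok": true, "gnomad_allele_count": 0, "maf_by_source": {}}, "sample_id": "CASE_USH2A", "scores": {"cadd_phred": 28.3, "rank_scores": {"DANN": 0.75, "EigenPC": 0.75, "FATHMM": 0.75, "LRT": 0.75, "MCAP": 0.75, "MetaLR": 0.75, "MetaSVM": 0.75, "MutPred": 0.75, "MutationAssessor": 0.75, "MutationTaster": 0.75, "PROVEAN": 0.75, "Polyphen2HDIV": 0.75, "Polyphen2HVAR": 0.75, "SIFT": 0.75, "VEST3": 0.2}, "revel": 0.767}, "upstream_calls": [{"criterion": "PM2", "met": true, "rationale": "Variant not found in gnomAD genomes", "strength": "Supporting"}, {"criterion": "PP4", "met": true, "rationale": "clinical diagnosis of Usher syndrome (case specific)", "strength": "Supporting"}], "zygosity": "het"}
{"annotation": "USH2A:NM_206933.4:c.2299del", "clinvar": {"classification": "P", "n_submissions": 20, "stars": 3}, "consequence": "frameshift", "hgvs_p": "p.(Glu767Serfs*21)", "lof": {"exon_in_relevant_transcript": true, "fraction_protein_removed": 0.85, "lof_frequent_in_population": false, "lof_type": "frameshift", "nmd_predicted": true, "pathogenic_variants_in_truncated_region": null, "splice_rescue_possible": null, "truncated_region_critical": null}, "panel": "FIXTURE", "population": {"coverage_ok": true, "maf_by_source": {}}, "sample_id": "CASE_USH2A", "scores": {"rank_scores": {}}, "upstream_calls": [{"criterion": "PM2", "met": true, "rationale": "", "strength": "Supporting"}, {"criterion": "PP5", "met": true, "rationale": "ClinVar classifies this variant as Pathogenic", "strength": "Supporting"}], "zygosity": "het"}
{"annotation": "CELSR1:NM_014246.4:c.5165G>A", "clinvar": null, "consequence": "missense", "hgvs_p": "p.(Arg1722Gln)", "lof": null, "panel": "FIXTURE", "population": {"coverage_ok": true, "gnomad_allele_count": 2, "maf_by_source": {}}, "sample_id": "CASE_CELSR1", "scores": {"cadd_phred": 29.1, "rank_scores": {"DANN": 0.75, "EigenPC": 0.75, "FATHMM": 0.75, "LRT": 0.75, "MCAP": 0.75, "MetaLR": 0.75, "MetaSVM": 0.75, "MutPred": 0.75, "MutationAssessor": 0.75, "MutationTaster": 0.75, "PROVEAN": 0.75, "Polyphen2HDIV": 0.75, "Polyphen2HVAR": 0.75, "SIFT": 0.2, "VEST3": 0.2}, "revel": 0.723}, "upstream_calls": [{"criterion": "PM2", "met": true, "rationale": "GnomAD genomes allele count = 2 is less than 5", "strength": "Supporting"}], "zygosity": "het"}
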