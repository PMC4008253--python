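"""Run every stage end to end and inspect the summary report.

Equivalent to `markermine run-all --outdir markermine_out --seed 1` on the
command line: simulate, mine SSRs, predict ORFs, design primers, call SNPs,
run electronic PCR, partition compartments and write the report.
"""

from markermine.pipeline import load_config, run_pipeline

config = load_config(None, {"sim.n_transcripts": 15, "seed": 1})
result = run_pipeline(config, "markermine_out")

s = result.summary
print("artifacts written to markermine_out/ (TSV tables, FASTA/FASTQ/SAM)")
print(f"transcripts: {s.counts['n_transcripts']}, reads: {s.counts['n_reads']}")
print(f"SSRs: {s.counts['n_ssrs']} "
      f"({s.percents['sequences_with_ssr']}% of sequences carry one; "
      f"{s.percents['ssrs_with_primers']}% have a designable primer pair)")
print(f"SSRs inside the predicted ORF: {s.percents.get('ssrs_in_orf')}%; "
      f"frame-preserving among those: {s.percents.get('frame_preserving_in_orf')}%")
print(f"SNPs: {s.counts['n_snps']} "
      f"({s.counts['n_transitions']} transitions / {s.counts['n_transversions']} transversions); "
      f"1 SNP per {s.ratios['bases_per_snp']} bases")
print(f"chloroplast-flagged transcripts: {s.counts['n_chloroplast']}")
print(f"planted-truth check: {s.counts['ssr_truth_tp']} SSRs and "
      f"{s.counts['snp_truth_tp']} SNPs recovered, "
      f"{s.counts['snp_truth_fn']} missed, {s.counts['snp_truth_fp']} spurious")

# Every percentage in summary.tsv is stored beside its numerator and
# denominator, so each printed figure can be recomputed by hand.
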