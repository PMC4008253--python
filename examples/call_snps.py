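"""Call confidence-filtered SNPs from simulated 454-style reads.

Simulates 30x reads over transcripts carrying one biallelic site each
(minor allele fraction 0.3), stacks them into pileups and applies the
minority-allele filter: coverage >= 8x, minor allele in >= 4 reads and
>= 10% of the depth.
"""

from markermine import build_pileup, call_snps, snp_density, titv_summary
from markermine.synthetic_data import SimulationConfig, simulate_reads, simulate_transcripts

cfg = SimulationConfig(
    n_transcripts=8,
    auto_variants_per_transcript=1,
    minor_fraction_range=(0.3, 0.3),
    coverage_target=30.0,
    seed=2,
)
transcripts, truth = simulate_transcripts(cfg)
reads, alignments = simulate_reads(transcripts, truth, cfg)

columns = build_pileup(alignments, transcripts)
calls = call_snps(columns)

print(f"{'transcript':<10}{'pos':<7}{'alleles':<9}{'minor/depth':<13}class")
for c in calls:
    print(f"{c.ref_id:<10}{c.pos + 1:<7}{c.major_allele}/{c.minor_allele:<7}"
          f"{c.minor_count}/{c.depth:<11}{c.klass}")

t = titv_summary(calls)
total_bases = sum(len(r.residues) for r in transcripts)
print(f"\n{len(calls)} SNPs from {len(truth.planted_snps)} planted sites; "
      f"{t.n_transitions} transitions ({t.transition_percent}%), "
      f"{t.n_transversions} transversions ({t.transversion_percent}%)")
print(f"density: 1 SNP per {snp_density(total_bases, len(calls))} bases")

# Positions are printed 1-based. With error-free reads every called site is
# a planted one; the minor/depth column shows the read evidence that passed
# the three filter thresholds.
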