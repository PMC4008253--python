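"""Mine microsatellites from simulated transcripts and classify their topography.

Generates 10 transcripts with planted repeats and ORFs, scans them with the
standard minimum-repeat thresholds (5x di-, 4x tri-, 3x tetra/penta/hexa-)
and reports each locus with its ORF context and frame effect.
"""

from markermine import find_ssrs, find_longest_orf, classify_ssr_location, is_frame_preserving
from markermine.synthetic_data import SimulationConfig, SSRPlant, simulate_transcripts

cfg = SimulationConfig(
    n_transcripts=10,
    ssr_plants=[SSRPlant("ACC", 5), SSRPlant("CA", 5)],
    orf_fraction=0.6,
    seed=1,
)
transcripts, truth = simulate_transcripts(cfg)

print(f"{'marker':<12}{'motif':<8}{'repeats':<9}{'interval':<14}{'location':<9}frame-preserving")
for rec in transcripts:
    orf = find_longest_orf(rec, min_len=90)
    for ssr in find_ssrs(rec):
        loc = classify_ssr_location(ssr, orf)
        frame = "Y" if is_frame_preserving(ssr) else "N"
        marker = f"{ssr.seq_id}{ssr.marker_suffix}"
        print(f"{marker:<12}{ssr.canonical_motif:<8}{ssr.repeat_count:<9}"
              f"[{ssr.start},{ssr.end})    {loc:<9}{frame}")

# Each line is one perfect tandem repeat: its strand-as-found canonical
# motif, repeat count, 0-based interval, whether it lies wholly inside the
# predicted coding region, and whether its length is a codon multiple (so
# repeat-count variation would not shift the reading frame).
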