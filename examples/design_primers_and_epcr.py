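"""Design SSR-flanking primers and predict repeat-length polymorphism in silico.

Plants an (ACC)5 repeat in a 600 bp transcript, designs a unique primer pair
around it (100-300 bp product, 18-24-mers, matched Tm), then simulates two
haplotypes differing by one repeat unit and asks whether per-read electronic
PCR detects the 3 bp product-size difference.
"""

from markermine import amplify, design_primer_pair, epcr_polymorphism, find_ssrs
from markermine.synthetic_data import (
    SimulationConfig,
    SSRPlant,
    haplotype_reads,
    simulate_transcripts,
    ssr_length_haplotypes,
)

cfg = SimulationConfig(n_transcripts=1, length_range=(600, 600),
                       ssr_plants=[SSRPlant("ACC", 5)], seed=4)
(template,), truth = simulate_transcripts(cfg)
ssr = truth.planted_ssrs[0]

pair = design_primer_pair(template, ssr)
print(f"SSR: ({ssr.unit}){ssr.repeat_count} at [{ssr.start},{ssr.end})")
print(f"forward  5'-{pair.fwd_seq}-3'  Tm {pair.fwd_tm:.1f} C, GC {pair.fwd_gc:.2f}")
print(f"reverse  5'-{pair.rev_seq}-3'  Tm {pair.rev_tm:.1f} C, GC {pair.rev_gc:.2f}")

amplicon = amplify(template, pair)[0]
print(f"template amplicon: {amplicon.length} bp (reported product size {pair.product_size} bp)")

hap1, hap2 = ssr_length_haplotypes(template, ssr, k_units=1)
reads = haplotype_reads(hap1, hap2, n_reads=6, seed=9)
call = epcr_polymorphism(reads, pair)
print(f"ePCR over {call.supporting_reads} reads: product lengths "
      f"{sorted(set(call.product_lengths))} -> polymorphic = {call.polymorphic}")

# The two haplotypes differ by one ACC unit (3 bp >= the 2 bp calling
# threshold), so the predictor flags the marker as polymorphic; with k=0 the
# lengths would be identical and the call negative.
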