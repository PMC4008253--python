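# markermine

Functional molecular-marker discovery from assembled transcript sequences,
aimed at non-model plants characterised with EST/454-style RNA-Seq: mine
microsatellites (SSRs), place them relative to the putative coding region,
design flanking primer pairs, call high-confidence SNPs from read pileups,
predict repeat-length polymorphism by electronic PCR over the raw reads,
and separate chloroplast-derived transcripts from the nuclear marker panel.
A seeded 454-style read simulator with planted ground truth makes every
stage testable end to end.

## The computation

- **SSR mining.** A microsatellite is a perfect, maximal tandem repeat of a
  primitive 2–6 bp unit meeting the standard minimum repeat counts
  {di: 5, tri: 4, tetra: 3, penta: 3, hexa: 3}. Motifs are reported
  strand-as-found, keyed by the lexicographically minimal rotation (so a
  CAC-context repeat reports motif `acc`).
- **ORF topography.** The putative coding region is the longest
  ATG-initiated ORF over all six frames (open 3′ ends allowed for truncated
  assemblies). An SSR is *in-ORF* when fully contained in that interval and
  *frame-preserving* when `unit_len × repeat_count ≡ 0 (mod 3)`.
- **Primer design.** Deterministic constraint search: 18–24-mers, 40–60%
  GC, Tm 50–65 °C (Wallace rule below 14 bp, else
  `64.9 + 41·(GC − 16.4)/len`), ≤ 5 °C pair difference, unique annealing
  across both strands, 100–300 bp products; the feasible pair closest to a
  200 bp product wins.
- **SNP calling.** A pileup column is a SNP when depth ≥ 8×, the minority
  allele is seen in ≥ 4 reads and in ≥ 10% of the depth (all inclusive).
  Calls are classed as transitions (A↔G, C↔T) or transversions, with
  per-pair shares and a bases-per-SNP density.
- **Electronic PCR polymorphism.** A marker supported by ≥ 3 reads whose
  per-read amplicon sizes differ by ≥ 2 bp is predicted polymorphic.
- **Compartment partitioning.** Canonical 21-mer containment against a
  plastid reference (threshold 0.5) flags chloroplast transcripts; an
  importer for 12-column tabular similarity hits covers alignment-based
  screens.

## Worked example

```
$ python examples/design_primers_and_epcr.py
SSR: (ACC)5 at [461,476)
forward  5'-CTGATCCACTCTTAGAGTCG-3'  Tm 51.8 C, GC 0.50
reverse  5'-ATCATAGTCTGGAAGCCTGC-3'  Tm 51.8 C, GC 0.50
template amplicon: 200 bp (reported product size 200 bp)
ePCR over 6 reads: product lengths [200, 203] -> polymorphic = True
```

The designed pair re-amplifies its template to a single 200 bp product; two
simulated haplotypes differing by one ACC unit give per-read products of
200 and 203 bp, a 3 bp difference ≥ the 2 bp threshold, so the marker is
predicted polymorphic. The other scripts in `examples/` walk through SSR
mining and topography, SNP calling, compartment classification and the full
pipeline; `markermine run-all --outdir out --seed 1` runs everything from
the shell, writing TSV marker tables and a key-value summary in which every
percentage sits next to its numerator and denominator.

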