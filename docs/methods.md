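# Methods

## Scope and data model

markermine re-implements the in-silico marker-discovery computation used in
EST/454 transcriptome characterisation studies of non-model plants:
microsatellite (SSR) mining, ORF topography, primer selection, pileup SNP
calling, electronic-PCR polymorphism prediction and chloroplast/nuclear
partitioning. Inputs are plain-text FASTA transcripts, FASTQ reads, a
minimal SAM dialect for read-to-transcript alignments, and TSV tables.
Internally every coordinate is 0-based half-open; reported tables use
1-based inclusive positions, the convention of published marker sheets.
Residues outside A/C/G/T/N are rejected rather than masked, because the
scanners assume a five-letter alphabet. The SAM dialect accepts only
M/I/D/S operations (soft clips are trimmed on ingest); transcript-space
alignments need no splicing or hard-clip semantics.

## SSR mining

An SSR is a *perfect, maximal* tandem run of a *primitive* 2–6 bp unit
(`unit` is primitive when it is not a whole-number repetition of a shorter
word; this prevents (AT)×6 from also being reported as (ATAT)×3, and
excludes homopolymers entirely, which are not SSR classes here). Minimum
repeat counts default to five for dinucleotides, four for trinucleotides
and three for tetra-, penta- and hexanucleotides. The scanner finds, for
each unit length u, the maximal regions satisfying `s[j] == s[j-u]`; a
region of length L starting at `a` yields the locus `[a, a + u·⌊L/u⌋)` when
the starting unit is primitive and the count meets its threshold. A run
whose smallest period is p also satisfies the condition at every multiple
of p, but there its starting unit is non-primitive, so each run is reported
exactly once, leftmost. Runs are broken at N. Overlapping runs with
different primitive units (e.g. (AT)5 abutting (TG)5 sharing one base) are
both reported. Motifs are aggregated by the lexicographically minimal
rotation of the unit, lowercased, with *no* reverse-complement folding:
published marker sheets report motifs strand-as-found (`gtc`, `ttc`), and
folding would merge classes those sheets keep apart. Imperfect/compound
repeats are out of scope.

## ORF topography

The putative coding region is the longest ATG-initiated ORF across the six
frames. A candidate runs from an ATG to the first in-frame stop (TAA, TAG,
TGA; the stop codon is excluded from the interval) or to the last complete
codon of the sequence (`has_stop = False`), since EST assemblies are often
3′-truncated. A codon containing N terminates extension without a stop.
Ties favour the forward strand, then the smaller forward-strand start. The
ATG-to-stop definition (rather than stop-to-stop) is a documented design
choice; the function takes a `min_len` parameter (default 0) and the
pipeline applies 90 bp, a common floor that suppresses spurious short ORFs
in random sequence. An SSR is IN_ORF only under full containment: a repeat
crossing the start or stop boundary cannot shift the coding frame, which is
the biological point of the classification. Frame preservation is
`unit_len × repeat_count ≡ 0 (mod 3)`; tri- and hexanucleotide repeats are
frame-preserving for every count.

## Primer design

Primer3's thermodynamic model is deliberately *not* reproduced. The claims
this pipeline supports reduce to flank sufficiency and product-size
windows, which transparent hard constraints capture deterministically:
primer length 18–24 bp, GC 0.40–0.60, Tm in 50–65 °C computed by the
Wallace rule (2·AT + 4·GC) below 14 bp and `64.9 + 41·(GC − 16.4)/len`
otherwise, ≤ 4 bp homopolymers, ≥ 3 bp clearance to the SSR, ≤ 5 °C pair Tm
difference, product 100–300 bp. Uniqueness is within-template only (an
EST-by-EST design context): a candidate must occur exactly once counting
both strands. Among feasible pairs the selection minimises
|product − 200 bp|, then pair Tm difference, then the leftmost forward
start — fully deterministic. Candidates containing N are rejected, which
also answers how N runs in flanks are handled: they simply cannot host a
primer.

## SNP calling

Pileups are built from alignment records: M ops contribute one base per
reference column, I ops nothing, D ops skip columns; N bases are excluded
from counts. The confidence filter is read-count based and quality-blind
(no Phred weighting): depth ≥ 8×, minority allele in ≥ 4 reads, minority
fraction ≥ 10% of depth, all thresholds inclusive — a minority fraction of
exactly 0.10 passes, reading "at least" literally. Count ties are labelled
alphabetically. Columns with a third observed allele still yield a single
biallelic call on the top two, flagged `multiallelic`. "Putative" SNPs (the
pre-filter set) are defined as any column with ≥ 2 observed alleles.
Transitions are A↔G and C↔T; everything else is a transversion. Densities
are `round_half_up(total bases / calls)`. Indels are never called; I/D ops
only shape the pileup.

## Electronic PCR

`amplify` is exact-match (zero mismatches, a documented hook exists only as
a parameter default): the forward primer must occur verbatim, the reverse
primer's reverse complement downstream of it, each forward site pairing
with the nearest compatible reverse site, capped at 5 kb. Only reads
containing *both* primer sites support a polymorphism call — per-read
amplification requires full containment. A marker is polymorphic when ≥ 3
supporting reads yield product lengths differing by ≥ 2 bp; fewer reads is
"insufficient reads", never polymorphic. The `IS(2)` output flag marks
calls with exactly two distinct product lengths (an interpretation of the
marker-sheet legend). Because homopolymer indel errors can fabricate ≥ 2 bp
differences, an optional guard (`require_replicated_lengths`, default off)
demands each distinct length be seen twice.

## Compartment partitioning

The alignment-based chloroplast screen of the original workflow is replaced
by a transparent k-mer containment classifier: canonical 21-mers (min of
k-mer and reverse complement; odd k so no k-mer is its own complement) of a
plastid reference form an index, and a unigene is chloroplast when ≥ 50% of
its canonical k-mers are contained. Nucleotide k-mers have no analogue of
translated (TBLASTX-style) similarity, a known sensitivity gap of the
substitute; `import_hits` ingests a 12-column tabular hit file with an
e-value cutoff for users who want the alignment-based criterion.
Downstream tables carry the chloroplast flag so nuclear-only summaries can
exclude flagged records.

## The simulator

The generator emulates the study conditions rather than 454 physics: i.i.d.
background bases at a configurable GC fraction; planted perfect repeats
with a guaranteed clean flank; planted ATG…stop ORFs; biallelic sites where
each read draws the alternative allele independently with probability
`minor_fraction` (so per-site minor counts are Binomial(depth, m) — the
minimal model of a pooled sample of outbred individuals); reads of
Normal(421, 60) bp truncated to [50, transcript length], uniform starts,
Bernoulli(½) strands, per-base substitution errors, and optional
homopolymer indels (the dominant 454 artifact; one event per affected run
of ≥ 3 bp, default off). Every output is a deterministic function of the
seed.

Two choices make recovery tests exact rather than statistical. First, each
transcript is rejection-sampled until the SSR scanner reports exactly the
planted loci and, when an ORF is planted, the longest-ORF finder returns
the planted region — so truth tables and scanner semantics coincide by
construction. Second, auto-planted variant positions are drawn from the
central half of the transcript: with 421 bp reads on ~600 bp transcripts,
coverage decays linearly toward the ends, and a depth-thresholded filter
cannot be meaningfully scored where the design depth is unreachable.

What the simulator does *not* model — flowgram noise, expression-level
variation, chimeric reads, assembly errors, more than two alleles per
site — bounds what passing tests show: they validate the computation under
its stated assumptions, not robustness to real 454 artefacts beyond the
substitution/homopolymer error knobs.

A consequence of the Binomial allele model worth stating: at coverage c and
minor fraction m, a planted site is recoverable only when the Binomial tail
keeps the minor count ≥ 4 and ≥ 10%; near m ≈ 0.2 and c ≈ 30–40 a fraction
of a percent of sites fall below the count threshold by sampling alone, so
measured SNP recall sits just under 1.0 (0.997 over 1,000 planted sites in
the shipped acceptance run) while precision is exactly 1.0 on error-free
reads. This is a property of the filter under the stated conditions, not of
the implementation.

## Problem sizes and determinism

The shipped tests and the acceptance script use 20 replicates of 50
transcripts (500–700 bp) at 30× coverage, 200-template primer batches and
≥ 1,000-instance oracle comparisons — sizes at which every brute-force
oracle is still exhaustive and a full run completes in about a minute.
Rounding of reported percentages and ratios is round-half-up (ties away
from zero) at the stated precision, chosen over banker's rounding because
published marker tables mix conventions; raw counts are always printed
beside percentages so any figure can be recomputed. All randomness flows
from numpy `default_rng` seeded by the configuration; reruns are
byte-identical, and stage subcommands recompute upstream stages in memory
from the seeded configuration instead of reading artifacts back.
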