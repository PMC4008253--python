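"""Seeded generator of transcripts and 454-style reads with planted truth.

The simulator emulates the raw material of an EST marker-discovery study:
assembled transcripts carrying planted perfect tandem repeats, planted
ATG...stop ORFs and biallelic variant sites, plus pyrosequencing-style reads
(mean length 421 bp by default, configurable substitution and
homopolymer-indel error rates) with their true placements. Every output is
fully determined by the seed.

Planted features are made exact, not statistical: each transcript is
rejection-sampled until the SSR scanner reports exactly the planted loci and
(when an ORF is planted) the longest-ORF finder returns the planted region.
At a planted variant site each read draws the alternative allele
independently with probability ``minor_fraction``, so the per-site minor
read count is Binomial(depth, minor_fraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import AlignmentRecord, SeqRecord, reverse_complement
from .orf_topography import ORFRegion, find_longest_orf
from .ssr_miner import SSRLocus, SSRThresholds, find_ssrs

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass
class SSRPlant:
    """One tandem repeat planted in every transcript: a 2-6 bp primitive unit,
    its repeat count, and the minimum clean flank kept on both sides."""

    unit: str
    repeat_count: int
    flank_min: int = 40

    def __post_init__(self) -> None:
        self.unit = self.unit.upper()
        if not (2 <= len(self.unit) <= 6) or set(self.unit) - set("ACGT"):
            raise ConfigError(f"SSR unit {self.unit!r} must be a 2-6-mer over A,C,G,T")
        if self.repeat_count < 2:
            raise ConfigError("repeat_count must be >= 2")

    @property
    def length(self) -> int:
        return len(self.unit) * self.repeat_count


@dataclass
class VariantPlant:
    """A biallelic site: reads draw ``alt`` with probability ``minor_fraction``."""

    transcript_index: int
    position: int
    ref: str
    alt: str
    minor_fraction: float

    def __post_init__(self) -> None:
        if not (0 < self.minor_fraction <= 0.5):
            raise ConfigError("minor_fraction must be in (0, 0.5]")
        if self.ref == self.alt or {self.ref, self.alt} - set("ACGT"):
            raise ConfigError(f"alleles must be two distinct bases, got {self.ref}/{self.alt}")


@dataclass
class PlantedSNP:
    seq_id: str
    position: int
    ref: str
    alt: str
    minor_fraction: float


@dataclass
class SimulationConfig:
    n_transcripts: int = 50
    length_range: tuple[int, int] = (500, 700)
    gc_fraction: float = 0.5
    ssr_plants: list[SSRPlant] = field(default_factory=list)
    orf_fraction: float = 0.0
    orf_length: int = 300
    variant_plants: list[VariantPlant] = field(default_factory=list)
    #: convenience: plant this many variants per transcript at positions drawn
    #: from the central half, with minor fractions uniform over the range below
    auto_variants_per_transcript: int = 0
    minor_fraction_range: tuple[float, float] = (0.2, 0.5)
    read_mean_len: float = 421.0
    read_len_sd: float = 60.0
    coverage_target: float = 30.0
    subst_error_rate: float = 0.0
    homopolymer_indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 50 or hi < lo:
            raise ConfigError(f"bad length_range {self.length_range}")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ConfigError("gc_fraction must be in [0, 1]")
        if self.orf_fraction and (self.orf_length % 3 or self.orf_length < 9):
            raise ConfigError("orf_length must be a multiple of 3, >= 9")
        for p in self.ssr_plants:
            if 2 * p.flank_min + p.length > lo:
                raise ConfigError(
                    f"planted SSR ({p.unit} x {p.repeat_count}) with flank_min "
                    f"{p.flank_min} cannot fit in a {lo} bp transcript"
                )
        if not (0.0 <= self.orf_fraction <= 1.0):
            raise ConfigError("orf_fraction must be in [0, 1]")
        if self.coverage_target <= 0:
            raise ConfigError("coverage_target must be > 0")


@dataclass
class TruthTables:
    """Planted ground truth; all coordinates 0-based half-open."""

    planted_ssrs: list[SSRLocus] = field(default_factory=list)
    planted_orfs: list[ORFRegion] = field(default_factory=list)
    planted_snps: list[PlantedSNP] = field(default_factory=list)
    read_placements: list[AlignmentRecord] = field(default_factory=list)


def random_sequence(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    return "".join(rng.choice(BASES, size=length, p=[p_at, p_gc, p_gc, p_at]))


_STOPS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]


def _break_period(seq: list[str], pos: int, other: int, rng: np.random.Generator) -> None:
    """Ensure seq[pos] != seq[other] so a planted repeat cannot extend."""
    if 0 <= pos < len(seq) and seq[pos] == seq[other]:
        choices = [b for b in "ACGT" if b != seq[other]]
        seq[pos] = choices[int(rng.integers(0, 3))]


def _plant_transcript(
    tid: str,
    length: int,
    cfg: SimulationConfig,
    plant_orf: bool,
    explicit_variants: list[VariantPlant],
    rng: np.random.Generator,
    max_attempts: int = 400,
) -> tuple[SeqRecord, list[SSRLocus], ORFRegion | None]:
    thresholds = SSRThresholds()
    for _ in range(max_attempts):
        seq = list(random_sequence(rng, length, cfg.gc_fraction))
        orf_region: ORFRegion | None = None
        blocked: list[tuple[int, int]] = []  # intervals SSRs must not touch
        if plant_orf:
            if cfg.orf_length + 3 > length:
                raise ConfigError(f"orf_length {cfg.orf_length} does not fit in {length} bp")
            o_start = int(rng.integers(0, length - cfg.orf_length - 3 + 1))
            seq[o_start : o_start + 3] = list("ATG")
            for cpos in range(o_start + 3, o_start + cfg.orf_length, 3):
                if "".join(seq[cpos : cpos + 3]) in _STOPS:
                    seq[cpos : cpos + 3] = list(_NONSTOP_CODONS[int(rng.integers(0, 61))])
            stop = _STOPS[int(rng.integers(0, 3))]
            seq[o_start + cfg.orf_length : o_start + cfg.orf_length + 3] = list(stop)
            orf_region = ORFRegion(tid, o_start, o_start + cfg.orf_length, "+", o_start % 3, True)
            blocked = [(o_start, o_start + 3), (o_start + cfg.orf_length, o_start + cfg.orf_length + 3)]

        planted: list[SSRLocus] = []
        ok = True
        for plant in cfg.ssr_plants:
            placed = False
            for _try in range(60):
                pos = int(rng.integers(plant.flank_min, length - plant.flank_min - plant.length + 1))
                iv = (pos - 6, pos + plant.length + 6)
                if any(iv[0] < e and b < iv[1] for b, e in blocked):
                    continue
                seq[pos : pos + plant.length] = list(plant.unit * plant.repeat_count)
                u = len(plant.unit)
                _break_period(seq, pos - 1, pos - 1 + u, rng)
                _break_period(seq, pos + plant.length, pos + plant.length - u, rng)
                blocked.append((pos, pos + plant.length))
                planted.append(SSRLocus(tid, pos, pos + plant.length, plant.unit, plant.repeat_count))
                placed = True
                break
            if not placed:
                ok = False
                break
        if not ok:
            continue

        for v in explicit_variants:
            if not (0 <= v.position < length):
                raise ConfigError(f"variant position {v.position} outside transcript {tid} ({length} bp)")
            if any(b <= v.position < e for b, e in blocked):
                raise ConfigError(f"variant at {v.position} collides with a planted feature in {tid}")
            seq[v.position] = v.ref

        rec = SeqRecord(tid, "".join(seq))
        found = {(l.start, l.end, l.unit) for l in find_ssrs(rec, thresholds)}
        want = {(l.start, l.end, l.unit) for l in planted}
        if found != want:
            continue
        if plant_orf:
            got = find_longest_orf(rec)
            if got is None or (got.start, got.end, got.strand, got.has_stop) != (
                orf_region.start,
                orf_region.end,
                "+",
                True,
            ):
                continue
        planted.sort(key=lambda l: l.start)
        for i, l in enumerate(planted):
            l.index_in_seq = i
        return rec, planted, orf_region
    raise ConfigError(f"could not realise planted features in {tid} after {max_attempts} attempts")


def simulate_transcripts(config: SimulationConfig) -> tuple[list[SeqRecord], TruthTables]:
    """Generate transcripts with planted SSRs, ORFs and variant sites."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.length_range
    records: list[SeqRecord] = []
    truth = TruthTables()
    explicit_by_tx: dict[int, list[VariantPlant]] = {}
    for v in config.variant_plants:
        explicit_by_tx.setdefault(v.transcript_index, []).append(v)
    for t in range(config.n_transcripts):
        tid = f"tx{t:04d}"
        length = int(rng.integers(lo, hi + 1))
        plant_orf = bool(rng.random() < config.orf_fraction)
        explicit = explicit_by_tx.get(t, [])
        rec, planted, orf = _plant_transcript(tid, length, config, plant_orf, explicit, rng)
        records.append(rec)
        truth.planted_ssrs.extend(planted)
        if orf is not None:
            truth.planted_orfs.append(orf)
        for v in explicit:
            truth.planted_snps.append(PlantedSNP(tid, v.position, v.ref, v.alt, v.minor_fraction))
        if config.auto_variants_per_transcript:
            ssr_ivs = [(l.start - 2, l.end + 2) for l in planted]
            used: set[int] = set()
            lo_m, hi_m = config.minor_fraction_range
            for _ in range(config.auto_variants_per_transcript):
                for _try in range(100):
                    # central half: read coverage is flat there, so a planted
                    # site actually sees the configured depth
                    pos = int(rng.integers(length // 4, 3 * length // 4))
                    if pos in used or any(b <= pos < e for b, e in ssr_ivs):
                        continue
                    ref = rec.residues[pos]
                    alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                    mf = float(rng.uniform(lo_m, hi_m))
                    truth.planted_snps.append(PlantedSNP(tid, pos, ref, alt, mf))
                    used.add(pos)
                    break
    return records, truth


def _inject_substitutions(seq: list[str], rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        others = [b for b in "ACGT" if b != seq[i]]
        seq[i] = others[int(rng.integers(0, 3))]


def _inject_homopolymer_indels(
    seq: list[str], rate: float, rng: np.random.Generator
) -> tuple[list[str], list[tuple[int, str]]]:
    """One insertion or deletion per affected homopolymer run of >= 3 bp.

    Returns the mutated read and its CIGAR against the original window.
    """
    n = len(seq)
    events: dict[int, str] = {}  # position in original window -> 'I' | 'D'
    i = 0
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= 3 and rng.random() < rate:
            events[i] = "I" if rng.random() < 0.5 else "D"
        i = j
    if not events:
        return seq, [(n, "M")]
    out: list[str] = []
    cigar: list[tuple[int, str]] = []

    def push(op: str, k: int = 1) -> None:
        if cigar and cigar[-1][1] == op:
            cigar[-1] = (cigar[-1][0] + k, op)
        else:
            cigar.append((k, op))

    for pos in range(n):
        ev = events.get(pos)
        if ev == "D":
            push("D")
            continue
        out.append(seq[pos])
        push("M")
        if ev == "I":
            out.append(seq[pos])
            push("I")
    return out, cigar


def simulate_reads(
    transcripts: list[SeqRecord], truth: TruthTables, config: SimulationConfig
) -> tuple[list[SeqRecord], list[AlignmentRecord]]:
    """Draw 454-style reads and their true placements.

    Reads start uniformly along the transcript, lengths are
    Normal(read_mean_len, read_len_sd) truncated to [50, transcript length],
    strands Bernoulli(0.5). The returned alignments carry the read in
    reference orientation with the error-free placement; the FASTQ-facing
    records carry the read as sequenced (reverse complemented on '-').
    """
    rng = np.random.default_rng([config.seed, 1])
    snps_by_tx: dict[str, list[PlantedSNP]] = {}
    for v in truth.planted_snps:
        snps_by_tx.setdefault(v.seq_id, []).append(v)
    reads: list[SeqRecord] = []
    alignments: list[AlignmentRecord] = []
    for rec in transcripts:
        L = len(rec.residues)
        mean_eff = min(config.read_mean_len, L)
        n_reads = max(1, int(round(config.coverage_target * L / mean_eff)))
        local_snps = snps_by_tx.get(rec.id, [])
        for i in range(n_reads):
            rl = int(round(rng.normal(config.read_mean_len, config.read_len_sd)))
            rl = max(min(50, L), min(rl, L))
            start = int(rng.integers(0, L - rl + 1))
            window = list(rec.residues[start : start + rl])
            for v in local_snps:
                if start <= v.position < start + rl and rng.random() < v.minor_fraction:
                    window[v.position - start] = v.alt
            _inject_substitutions(window, config.subst_error_rate, rng)
            if config.homopolymer_indel_rate > 0:
                window, cigar = _inject_homopolymer_indels(
                    window, config.homopolymer_indel_rate, rng
                )
            else:
                cigar = [(rl, "M")]
            fwd_seq = "".join(window)
            strand = "-" if rng.random() < 0.5 else "+"
            read_id = f"{rec.id}_r{i:04d}"
            alignments.append(AlignmentRecord(read_id, rec.id, start, strand, cigar, fwd_seq))
            out_seq = reverse_complement(fwd_seq) if strand == "-" else fwd_seq
            reads.append(SeqRecord(read_id, out_seq, qualities=[30] * len(out_seq)))
    return reads, alignments


# ---------------------------------------------------------------------------
# Recovery scoring


@dataclass
class RecoveryRecord:
    n_truth: int
    n_calls: int
    tp: int
    fp: int
    fn: int
    precision: float | None  # None = not applicable (no calls)
    recall: float | None  # None = not applicable (no truth)


def evaluate_recovery(truth: TruthTables, calls: Sequence, kind: str) -> RecoveryRecord:
    """Score calls against planted truth.

    SNP calls match on (transcript, position); SSR loci match on
    (transcript, interval, canonical motif) — all exact.
    """
    if kind == "snp":
        truth_keys = {(v.seq_id, v.position) for v in truth.planted_snps}
        call_keys = {(c.ref_id, c.pos) for c in calls}
    elif kind == "ssr":
        truth_keys = {(l.seq_id, l.start, l.end, l.canonical_motif) for l in truth.planted_ssrs}
        call_keys = {(l.seq_id, l.start, l.end, l.canonical_motif) for l in calls}
    else:
        raise ValueError(f"kind must be 'snp' or 'ssr', got {kind!r}")
    tp = len(truth_keys & call_keys)
    fp = len(call_keys - truth_keys)
    fn = len(truth_keys - call_keys)
    return RecoveryRecord(
        n_truth=len(truth_keys),
        n_calls=len(call_keys),
        tp=tp,
        fp=fp,
        fn=fn,
        precision=tp / (tp + fp) if (tp + fp) else None,
        recall=tp / (tp + fn) if (tp + fn) else None,
    )


# ---------------------------------------------------------------------------
# Targeted fixtures


def ssr_length_haplotypes(
    template: SeqRecord, ssr: SSRLocus, k_units: int
) -> tuple[SeqRecord, SeqRecord]:
    """The template plus a second haplotype differing by ``k_units`` repeat
    units at the given SSR (inserted when positive, removed when negative)."""
    new_count = ssr.repeat_count + k_units
    if new_count < 1:
        raise ConfigError("cannot remove more repeat units than the SSR has")
    s = template.residues
    alt = s[: ssr.start] + ssr.unit * new_count + s[ssr.end :]
    return template, SeqRecord(template.id + "_hap2", alt)


def haplotype_reads(
    hap1: SeqRecord, hap2: SeqRecord, n_reads: int, seed: int = 0
) -> list[SeqRecord]:
    """Full-length reads drawn alternately from two haplotypes (hap1 first)."""
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        hap = hap1 if i % 2 == 0 else hap2
        seq = hap.residues
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append(SeqRecord(f"{hap1.id}_pr{i:03d}", seq))
    return reads


def make_chloroplast_reference(length: int = 20000, gc_fraction: float = 0.37, seed: int = 0) -> SeqRecord:
    """A synthetic stand-in for a plastid reference genome (random sequence at
    a plastid-like GC fraction); not derived from any real organellar genome."""
    rng = np.random.default_rng([seed, 7])
    return SeqRecord("cp_reference", random_sequence(rng, length, gc_fraction))


def chloroplast_transcripts(
    reference: SeqRecord, n: int, length_range: tuple[int, int] = (300, 600), seed: int = 0
) -> list[SeqRecord]:
    """Transcripts copied verbatim from slices of the plastid reference."""
    rng = np.random.default_rng([seed, 8])
    out = []
    L = len(reference.residues)
    for i in range(n):
        ln = int(rng.integers(length_range[0], length_range[1] + 1))
        start = int(rng.integers(0, L - ln + 1))
        out.append(SeqRecord(f"cptx{i:03d}", reference.residues[start : start + ln]))
    return out
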