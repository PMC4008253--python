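"""Flanking primer-pair selection for SSR loci.

Design is deliberately transparent rather than thermodynamic: hard
constraints on primer length, GC fraction, a Wallace-rule / length-adjusted
melting temperature, homopolymer content, within-template uniqueness and a
100-300 bp product window. Among all feasible pairs the choice is
deterministic: closest product size to 200 bp, then smallest pair Tm
difference, then leftmost forward start.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .io_formats import SeqRecord, reverse_complement
from .ssr_miner import SSRLocus


@dataclass
class PrimerConstraints:
    """Hard physical constraints applied to every candidate primer and pair.

    Defaults: 18-24 bp primers, 40-60% GC, Tm 50-65 C with at most 5 C
    difference within a pair, 100-300 bp products, homopolymers of at most
    4 bp, and at least 3 bp between a primer and the SSR it flanks.
    """

    primer_len: tuple[int, int] = (18, 24)
    gc_range: tuple[float, float] = (0.40, 0.60)
    tm_range: tuple[float, float] = (50.0, 65.0)
    max_pair_tm_diff: float = 5.0
    product_range: tuple[int, int] = (100, 300)
    max_homopolymer: int = 4
    min_gap_to_ssr: int = 3

    def __post_init__(self) -> None:
        if self.primer_len[0] > self.primer_len[1] or self.product_range[0] > self.product_range[1]:
            raise ValueError("empty primer length or product size range")
        if self.product_range[0] <= 2 * self.primer_len[0]:
            raise ValueError("product_range.min must exceed twice the minimum primer length")


@dataclass
class PrimerPair:
    """A designed pair; ``rev_seq`` is given 5'->3' on the opposite strand."""

    ssr_ref: str
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    product_size: int
    fwd_tm: float
    rev_tm: float
    fwd_gc: float
    rev_gc: float


def gc_content(seq: str) -> float:
    """Fraction of G+C residues."""
    if len(seq) < 2:
        raise ValueError("sequence too short for GC content")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temp(seq: str) -> float:
    """Wallace rule below 14 bp, length-adjusted GC formula at and above.

    Tm = 2(A+T) + 4(G+C) for short oligos; 64.9 + 41(GC - 16.4)/len otherwise.
    """
    if len(seq) < 2:
        raise ValueError("sequence too short for a melting temperature")
    gc = seq.count("G") + seq.count("C")
    at = len(seq) - gc
    if len(seq) < 14:
        return 2.0 * at + 4.0 * gc
    return 64.9 + 41.0 * (gc - 16.4) / len(seq)


def _max_homopolymer(seq: str) -> int:
    return max(len(list(g)) for _, g in groupby(seq))


def _acceptable_oligo(seq: str, template: str, c: PrimerConstraints) -> bool:
    if "N" in seq:
        return False
    if not (c.gc_range[0] <= gc_content(seq) <= c.gc_range[1]):
        return False
    if not (c.tm_range[0] <= melting_temp(seq) <= c.tm_range[1]):
        return False
    if _max_homopolymer(seq) > c.max_homopolymer:
        return False
    # unique annealing site: exactly one occurrence counting both strands
    # (a forward primer occurs verbatim; a reverse primer occurs as the
    # reverse complement of its annealing site)
    if template.count(seq) + template.count(reverse_complement(seq)) != 1:
        return False
    return True


def design_primer_pair(
    template: SeqRecord,
    ssr: SSRLocus,
    constraints: PrimerConstraints | None = None,
) -> PrimerPair | None:
    """Select the unique flanking primer pair for an SSR, or None.

    Every constraint in :class:`PrimerConstraints` is enforced; the SSR lies
    strictly between the primers with ``min_gap_to_ssr`` clearance.
    """
    c = constraints or PrimerConstraints()
    s = template.residues
    L = len(s)
    lmin, lmax = c.primer_len
    pmin, pmax = c.product_range

    # forward candidates end at least min_gap before the SSR
    fwd: list[tuple[int, int, float]] = []  # (start, length, tm)
    last_end = ssr.start - c.min_gap_to_ssr
    for length in range(lmin, lmax + 1):
        for f0 in range(0, last_end - length + 1):
            seq = s[f0 : f0 + length]
            if _acceptable_oligo(seq, s, c):
                fwd.append((f0, length, melting_temp(seq)))
    if not fwd:
        return None

    rev: list[tuple[int, int, float]] = []  # (rev_end, length, tm)
    first_start = ssr.end + c.min_gap_to_ssr
    for length in range(lmin, lmax + 1):
        for r0 in range(first_start, L - length + 1):
            site = s[r0 : r0 + length]
            rseq = reverse_complement(site)
            if _acceptable_oligo(rseq, s, c):
                rev.append((r0 + length, length, melting_temp(rseq)))
    if not rev:
        return None

    best: tuple | None = None
    for f0, flen, ftm in fwd:
        for rend, rlen, rtm in rev:
            size = rend - f0
            if not (pmin <= size <= pmax):
                continue
            tm_diff = abs(ftm - rtm)
            if tm_diff > c.max_pair_tm_diff:
                continue
            key = (abs(size - 200), tm_diff, f0, rend)
            if best is None or key < best[0]:
                best = (key, f0, flen, rend, rlen)
    if best is None:
        return None
    _, f0, flen, rend, rlen = best
    fwd_seq = s[f0 : f0 + flen]
    rev_seq = reverse_complement(s[rend - rlen : rend])
    return PrimerPair(
        ssr_ref=f"{ssr.seq_id}{ssr.marker_suffix}",
        fwd_seq=fwd_seq,
        rev_seq=rev_seq,
        fwd_start=f0,
        rev_end=rend,
        product_size=rend - f0,
        fwd_tm=melting_temp(fwd_seq),
        rev_tm=melting_temp(rev_seq),
        fwd_gc=gc_content(fwd_seq),
        rev_gc=gc_content(rev_seq),
    )


def has_sufficient_flank(
    template: SeqRecord, ssr: SSRLocus, constraints: PrimerConstraints | None = None
) -> bool:
    """True iff a constraint-satisfying unique primer pair exists for the SSR."""
    return design_primer_pair(template, ssr, constraints) is not None
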