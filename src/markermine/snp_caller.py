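"""Confidence-filtered biallelic SNP calling from read pileups.

A site is called when, over the reads aligned to it, total coverage is at
least 8x, the minority allele (second most common nucleotide) is seen in at
least 4 reads, and that minority count is at least 10% of the depth. All
three thresholds are inclusive. The call is biallelic on the top two alleles;
a flag marks columns where a third allele was also observed. No base-quality
weighting: the filter is purely read-count based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .io_formats import AlignmentRecord, SeqRecord
from .report import round_half_up

BASES = "ACGT"
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _BASE_CODE[ord(_b)] = _i


@dataclass
class SNPFilterParams:
    """Thresholds of the minority-allele confidence filter (all inclusive)."""

    min_coverage: int = 8
    min_minor_count: int = 4
    min_minor_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_minor_count < 1:
            raise ValueError("min_minor_count must be >= 1")
        if not (0 < self.min_minor_fraction <= 0.5):
            raise ValueError("min_minor_fraction must be in (0, 0.5]")


@dataclass
class PileupColumn:
    """Per-position A/C/G/T read counts; gaps and N are excluded."""

    ref_id: str
    pos: int
    counts: dict[str, int]

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass
class SNPCall:
    ref_id: str
    pos: int
    major_allele: str
    minor_allele: str
    major_count: int
    minor_count: int
    depth: int
    klass: str
    multiallelic: bool = False


def build_pileup(
    alignments: list[AlignmentRecord], refs: list[SeqRecord]
) -> list[PileupColumn]:
    """Stack aligned reads into per-position allele counts.

    M ops contribute one base per reference column, I ops contribute nothing,
    D ops skip reference columns. Only covered columns are returned, in
    (ref, position) order following the input reference order.
    """
    lengths = {r.id: len(r.residues) for r in refs}
    counts: dict[str, np.ndarray] = {r.id: np.zeros((len(r.residues), 4), dtype=np.int32) for r in refs}
    for aln in alignments:
        if aln.ref_id not in counts:
            raise ValueError(f"alignment of {aln.read_id!r} references unknown {aln.ref_id!r}")
        if aln.ref_end > lengths[aln.ref_id]:
            raise ValueError(f"alignment of {aln.read_id!r} exceeds reference bounds")
        arr = counts[aln.ref_id]
        q, r = 0, aln.ref_start
        for n, op in aln.cigar:
            if op == "M":
                codes = _BASE_CODE[np.frombuffer(aln.read_seq[q : q + n].encode(), dtype=np.uint8)]
                valid = codes < 4
                np.add.at(arr, (np.arange(r, r + n)[valid], codes[valid]), 1)
                q += n
                r += n
            elif op == "I":
                q += n
            else:  # D
                r += n
    columns: list[PileupColumn] = []
    for ref in refs:
        arr = counts[ref.id]
        covered = np.nonzero(arr.sum(axis=1) > 0)[0]
        for pos in covered:
            columns.append(
                PileupColumn(ref.id, int(pos), {b: int(arr[pos, i]) for i, b in enumerate(BASES) if arr[pos, i] > 0})
            )
    return columns


def call_snp(col: PileupColumn, params: SNPFilterParams | None = None) -> SNPCall | None:
    """Apply the minority-allele filter to one pileup column.

    Count ties are broken alphabetically for allele labelling; third and
    fourth alleles are ignored by the thresholds but flagged.
    """
    params = params or SNPFilterParams()
    depth = col.depth
    if depth < params.min_coverage:
        return None
    ranked = sorted(col.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < 2:
        return None
    (major, major_n), (minor, minor_n) = ranked[0], ranked[1]
    if minor_n < params.min_minor_count:
        return None
    if minor_n / depth < params.min_minor_fraction:
        return None
    return SNPCall(
        ref_id=col.ref_id,
        pos=col.pos,
        major_allele=major,
        minor_allele=minor,
        major_count=major_n,
        minor_count=minor_n,
        depth=depth,
        klass=classify_substitution(major, minor),
        multiallelic=len(ranked) > 2,
    )


def call_snps(
    columns: list[PileupColumn], params: SNPFilterParams | None = None
) -> list[SNPCall]:
    params = params or SNPFilterParams()
    return [c for c in (call_snp(col, params) for col in columns) if c is not None]


def putative_snp_columns(columns: list[PileupColumn]) -> list[PileupColumn]:
    """Pre-filter candidates: any column where at least two alleles are observed."""
    return [c for c in columns if len(c.counts) >= 2]


TRANSITIONS = ({"A", "G"}, {"C", "T"})


def classify_substitution(a: str, b: str) -> str:
    """A<->G and C<->T are transitions; the other four pairs transversions."""
    if a == b or a not in BASES or b not in BASES:
        raise ValueError(f"substitution requires two distinct bases in ACGT, got {a!r}, {b!r}")
    return "transition" if {a, b} in TRANSITIONS else "transversion"


#: Reporting order of the six unordered substitution pairs.
PAIR_ORDER = ("A/G", "C/T", "A/C", "C/G", "G/T", "A/T")


@dataclass
class TiTvSummary:
    pair_counts: dict[str, int]
    pair_percents: dict[str, int]
    n_transitions: int
    n_transversions: int
    transition_percent: int
    transversion_percent: int

    @property
    def total(self) -> int:
        return self.n_transitions + self.n_transversions


def titv_summary(calls: list[SNPCall]) -> TiTvSummary:
    """Per-pair counts with within-class whole-percent shares (round-half-up)."""
    pairs = Counter("/".join(sorted((c.major_allele, c.minor_allele))) for c in calls)
    pair_counts = {p: pairs.get(p, 0) for p in PAIR_ORDER}
    n_ti = pair_counts["A/G"] + pair_counts["C/T"]
    n_tv = sum(pair_counts[p] for p in PAIR_ORDER[2:])
    total = n_ti + n_tv
    pair_percents = {}
    for p in PAIR_ORDER:
        klass_total = n_ti if p in ("A/G", "C/T") else n_tv
        pair_percents[p] = int(round_half_up(100 * pair_counts[p] / klass_total, 0)) if klass_total else 0
    return TiTvSummary(
        pair_counts=pair_counts,
        pair_percents=pair_percents,
        n_transitions=n_ti,
        n_transversions=n_tv,
        transition_percent=int(round_half_up(100 * n_ti / total, 0)) if total else 0,
        transversion_percent=int(round_half_up(100 * n_tv / total, 0)) if total else 0,
    )


def snp_density(total_bases: int, n_snps: int) -> int | None:
    """Bases per SNP, rounded half-up; None (not applicable) when no SNPs."""
    if n_snps == 0:
        return None
    return int(round_half_up(total_bases / n_snps, 0))
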