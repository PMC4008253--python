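"""Perfect tandem repeat (SSR / microsatellite) detection.

A simple sequence repeat here is a perfect, maximal tandem run of a primitive
2-6 bp unit meeting a per-unit-length minimum repeat count. The defaults are
the thresholds standard in EST-SSR mining: five repeats for dinucleotides,
four for trinucleotides, three for tetra-, penta- and hexanucleotides.
Mononucleotide runs are not SSRs. Runs containing N are broken at the N.
Motifs are reported strand-as-found (no reverse-complement folding), keyed by
the lexicographically minimal rotation of the unit.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .io_formats import SeqRecord

DEFAULT_MIN_REPEATS = {2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass
class SSRThresholds:
    """Minimum repeat count per unit length (keys exactly 2..6)."""

    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))

    def __post_init__(self) -> None:
        if set(self.min_repeats) != {2, 3, 4, 5, 6}:
            raise ValueError(f"min_repeats keys must be exactly 2..6, got {sorted(self.min_repeats)}")
        if any(c < 2 for c in self.min_repeats.values()):
            raise ValueError("minimum repeat counts must be >= 2")


@dataclass
class SSRLocus:
    """A perfect tandem repeat: ``residues[start:end] == unit * repeat_count``."""

    seq_id: str
    start: int
    end: int
    unit: str
    repeat_count: int
    index_in_seq: int = 0

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def canonical_motif(self) -> str:
        return canonical_motif(self.unit)

    @property
    def marker_suffix(self) -> str:
        """Ordinal suffix (a, b, c, ...) by first occurrence within the sequence."""
        return chr(ord("a") + self.index_in_seq)


def canonical_motif(unit: str) -> str:
    """Lexicographically smallest rotation of ``unit``, lowercased.

    Aggregation key for motif class counts; e.g. CAC -> "acc". No
    reverse-complement folding: motifs are reported strand-as-found.
    """
    unit = unit.upper()
    if not unit or set(unit) - set("ACGT"):
        raise ValueError(f"motif unit {unit!r} must be non-empty over A,C,G,T")
    return min(unit[i:] + unit[:i] for i in range(len(unit))).lower()


def is_primitive(unit: str) -> bool:
    """True iff ``unit`` is not a whole-number repetition of a shorter unit."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssrs(record: SeqRecord, thresholds: SSRThresholds | None = None) -> list[SSRLocus]:
    """Scan one sequence for maximal perfect tandem repeats of 2-6 bp units.

    Each run is reported once, at its smallest (primitive) unit length; a run
    whose smallest period is p also satisfies the period condition at every
    multiple of p, but there the starting unit is non-primitive and skipped.
    """
    thresholds = thresholds or SSRThresholds()
    s = record.residues
    L = len(s)
    loci: list[SSRLocus] = []
    for u in range(2, 7):
        min_rep = thresholds.min_repeats[u]
        if L < u * min_rep:
            continue
        j = u  # first position compared against j - u
        region_start = 0
        while region_start < L - u * min_rep + 1:
            # extend the period-u region starting at region_start
            j = region_start + u
            while j < L and s[j] == s[j - u] and s[j] != "N":
                j += 1
            region_len = j - region_start
            count = region_len // u
            unit = s[region_start : region_start + u]
            if count >= min_rep and "N" not in unit and is_primitive(unit):
                loci.append(
                    SSRLocus(record.id, region_start, region_start + u * count, unit, count)
                )
            # next region cannot start before the mismatch position - u + 1
            region_start = max(region_start + 1, j - u + 1)
    loci.sort(key=lambda l: (l.start, l.end, l.unit_len))
    for i, locus in enumerate(loci):
        locus.index_in_seq = i
    return loci


def find_ssrs_many(records: list[SeqRecord], thresholds: SSRThresholds | None = None) -> list[SSRLocus]:
    out: list[SSRLocus] = []
    for rec in records:
        out.extend(find_ssrs(rec, thresholds))
    return out


def ssr_class_distribution(loci: list[SSRLocus]) -> dict[int, tuple[int, float]]:
    """Per unit-length (2..6) locus count and fraction of all loci."""
    counts = Counter(l.unit_len for l in loci)
    total = sum(counts.values())
    return {
        u: (counts.get(u, 0), counts.get(u, 0) / total if total else 0.0)
        for u in range(2, 7)
    }


def ssrs_per_sequence(loci: list[SSRLocus], n_sequences: int) -> dict[int, int]:
    """Histogram: number of sequences carrying exactly k SSRs, k = 1..max."""
    per_seq = Counter(l.seq_id for l in loci)
    hist = Counter(per_seq.values())
    if not hist:
        return {}
    return {k: hist.get(k, 0) for k in range(1, max(hist) + 1)}
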