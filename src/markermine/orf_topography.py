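"""Putative coding region prediction and SSR topography.

The putative coding region of a transcript is its longest open reading frame
across all six frames, where an ORF runs from an ATG to the first in-frame
stop codon (TAA/TAG/TGA), or to the end of the sequence for 3'-open
candidates typical of truncated EST assemblies. A codon containing N
terminates extension. An SSR is "in ORF" only when fully contained in the
predicted coding interval, and frame-preserving when its total length is a
multiple of three (so repeat-count variation cannot shift the downstream
reading frame).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import SeqRecord, reverse_complement
from .ssr_miner import SSRLocus

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass
class ORFRegion:
    """An ATG-initiated reading frame on the forward-strand coordinate system.

    ``[start, end)`` spans ATG through the codon before the stop (the stop
    codon itself is excluded); ``has_stop`` is False for 3'-open candidates.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    frame: int
    has_stop: bool

    @property
    def length(self) -> int:
        return self.end - self.start


def _scan_strand(seq: str, seq_id: str, strand: str) -> list[ORFRegion]:
    """All maximal ATG->stop/end candidates on one strand, in local coordinates."""
    L = len(seq)
    out: list[ORFRegion] = []
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, L - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
                continue
            if codon in STOP_CODONS:
                out.append(ORFRegion(seq_id, start, pos, strand, frame, True))
                start = None
            elif "N" in codon:
                if pos > start:
                    out.append(ORFRegion(seq_id, start, pos, strand, frame, False))
                start = None
        if start is not None:
            end = start + 3 * ((L - start) // 3)  # whole codons only
            out.append(ORFRegion(seq_id, start, end, strand, frame, False))
    return out


def find_longest_orf(record: SeqRecord, min_len: int = 0) -> ORFRegion | None:
    """Longest ATG-initiated ORF over all six frames, or None.

    Ties are broken in favour of the forward strand, then the smaller
    forward-strand start. Candidates shorter than ``min_len`` bases (default
    0; pipelines typically use 90) are discarded. Minus-strand candidates are
    reported in forward-strand coordinates with ``strand='-'``.
    """
    candidates = _scan_strand(record.residues, record.id, "+")
    L = len(record.residues)
    for orf in _scan_strand(reverse_complement(record.residues), record.id, "-"):
        # map [s, e) on the reverse complement to forward coordinates
        orf.start, orf.end = L - orf.end, L - orf.start
        candidates.append(orf)
    candidates = [c for c in candidates if c.length >= max(min_len, 3)]
    if not candidates:
        return None
    return min(candidates, key=lambda c: (-c.length, c.strand == "-", c.start))


def classify_ssr_location(ssr: SSRLocus, orf: ORFRegion | None) -> str:
    """"IN_ORF" iff the SSR interval is fully contained in the ORF, else "UTR".

    Partial overlap counts as UTR: a repeat crossing the start or stop
    boundary cannot shift the coding frame.
    """
    if orf is None:
        return "UTR"
    if ssr.seq_id != orf.seq_id:
        raise ValueError(f"SSR on {ssr.seq_id!r} classified against ORF on {orf.seq_id!r}")
    if orf.start <= ssr.start and ssr.end <= orf.end:
        return "IN_ORF"
    return "UTR"


def is_frame_preserving(ssr: SSRLocus) -> bool:
    """True iff unit length x repeat count is a multiple of three."""
    return (ssr.unit_len * ssr.repeat_count) % 3 == 0
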