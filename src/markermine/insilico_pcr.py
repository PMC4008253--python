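"""Deterministic electronic PCR and read-level SSR polymorphism prediction.

Amplification is exact-match: the forward primer must occur verbatim on the
forward strand and the reverse primer's reverse complement downstream of it;
each forward site pairs with its nearest compatible reverse site, capped at a
maximum product length. A marker is predicted polymorphic when at least
``min_reads`` reads each yield a product and the product lengths differ by at
least ``min_size_diff`` bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io_formats import SeqRecord, reverse_complement
from .primer_designer import PrimerPair


@dataclass
class EPCRParams:
    min_reads: int = 3
    min_size_diff: int = 2
    max_product: int = 5000
    #: when True, each distinct product length must be seen in >= 2 reads
    #: before it counts toward a polymorphism (guards against homopolymer
    #: indel read errors); off by default.
    require_replicated_lengths: bool = False


@dataclass
class Amplicon:
    template_id: str
    fwd_start: int
    rev_end: int
    product_seq: str

    @property
    def length(self) -> int:
        return self.rev_end - self.fwd_start


@dataclass
class EPCRPolymorphismCall:
    template_id: str
    marker_id: str
    supporting_reads: int
    product_lengths: list[int]
    polymorphic: bool
    status: str  # "ok" or "insufficient reads"

    @property
    def is_flag(self) -> str:
        """Marker sheet flag: "IS" for a polymorphic call, "IS(2)" when exactly
        two distinct product lengths were observed."""
        if not self.polymorphic:
            return ""
        return "IS(2)" if len(set(self.product_lengths)) == 2 else "IS"


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def amplify(template: SeqRecord, pair: PrimerPair, max_product: int = 5000) -> list[Amplicon]:
    """All products of a primer pair on one template, zero mismatches.

    One amplicon per forward site, ending at the nearest downstream reverse
    site within ``max_product``; empty when either primer has no site.
    """
    s = template.residues
    fwd_sites = _find_all(s, pair.fwd_seq)
    rev_site_seq = reverse_complement(pair.rev_seq)
    rev_ends = [r + len(rev_site_seq) for r in _find_all(s, rev_site_seq)]
    out: list[Amplicon] = []
    for f in fwd_sites:
        for rend in rev_ends:  # rev_ends is sorted ascending
            if rend - len(rev_site_seq) < f + len(pair.fwd_seq):
                continue
            if rend - f > max_product:
                break
            out.append(Amplicon(template.id, f, rend, s[f:rend]))
            break  # nearest compatible reverse site only
    return out


def epcr_polymorphism(
    reads: Iterable[SeqRecord],
    pair: PrimerPair,
    params: EPCRParams | None = None,
    template_id: str = "",
) -> EPCRPolymorphismCall:
    """Predict repeat-length polymorphism from per-read amplicon sizes.

    Each read is tested as-is and reverse complemented; a read supports the
    call when it yields at least one product (the shortest is recorded).
    """
    params = params or EPCRParams()
    lengths: list[int] = []
    for read in reads:
        products = amplify(read, pair, params.max_product)
        if not products:
            rc = SeqRecord(read.id, reverse_complement(read.residues))
            products = amplify(rc, pair, params.max_product)
        if products:
            lengths.append(min(p.length for p in products))
    supporting = len(lengths)
    if supporting < params.min_reads:
        return EPCRPolymorphismCall(template_id, pair.ssr_ref, supporting, lengths, False, "insufficient reads")
    considered = lengths
    if params.require_replicated_lengths:
        considered = [l for l in lengths if lengths.count(l) >= 2]
    polymorphic = bool(considered) and max(considered) - min(considered) >= params.min_size_diff
    return EPCRPolymorphismCall(template_id, pair.ssr_ref, supporting, lengths, polymorphic, "ok")


@dataclass
class EPCRBatchSummary:
    n_pairs: int
    n_eligible: int
    n_polymorphic: int

    @property
    def polymorphic_fraction(self) -> float | None:
        return self.n_polymorphic / self.n_eligible if self.n_eligible else None


def epcr_batch(
    read_groups: Mapping[str, list[SeqRecord]],
    panel: Iterable[tuple[str, PrimerPair]],
    params: EPCRParams | None = None,
) -> tuple[list[EPCRPolymorphismCall], EPCRBatchSummary]:
    """Run the polymorphism predictor over a panel of (template id, pair).

    Eligible = calls with enough supporting reads; the summary fraction is
    polymorphic / eligible.
    """
    params = params or EPCRParams()
    calls = [
        epcr_polymorphism(read_groups.get(tid, []), pair, params, template_id=tid)
        for tid, pair in panel
    ]
    eligible = sum(1 for c in calls if c.status == "ok")
    poly = sum(1 for c in calls if c.polymorphic)
    return calls, EPCRBatchSummary(len(calls), eligible, poly)
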