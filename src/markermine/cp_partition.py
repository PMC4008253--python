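"""Chloroplast vs nuclear partitioning of unigenes.

Two routes: a transparent, alignment-free k-mer containment classifier
against a chloroplast reference index (canonical 21-mers, containment
threshold 0.5), or import of an external 12-column tabular similarity search
(BLAST outfmt 6) with an e-value cutoff for users who want an
alignment-based screen. Note the k-mer route is nucleotide-level only; it
has no analogue of translated (protein-level) similarity and is therefore
less sensitive to diverged organellar sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io_formats import FormatError, SeqRecord, reverse_complement


@dataclass
class CompartmentCall:
    unigene_id: str
    containment: float | None
    is_chloroplast: bool
    method: str  # "kmer" or "imported"
    status: str = "ok"  # or "not-classifiable" (sequence shorter than k)


def _canonical_kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        yield min(kmer, reverse_complement(kmer))


def build_kmer_index(refs: list[SeqRecord], k: int = 21) -> set[str]:
    """Canonical k-mer set of the chloroplast reference(s).

    k must be odd (a canonical k-mer is then never its own reverse
    complement) and between 11 and 31.
    """
    if not refs:
        raise ValueError("cannot build a k-mer index from an empty reference set")
    if k % 2 == 0 or not (11 <= k <= 31):
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    index: set[str] = set()
    for ref in refs:
        index.update(_canonical_kmers(ref.residues, k))
    return index


def classify_compartment(
    unigene: SeqRecord, index: set[str], k: int = 21, threshold: float = 0.5
) -> CompartmentCall:
    """Containment of the unigene's canonical k-mers in the reference index."""
    kmers = list(_canonical_kmers(unigene.residues, k))
    if len(unigene.residues) < k or not kmers:
        return CompartmentCall(unigene.id, None, False, "kmer", "not-classifiable")
    containment = sum(1 for km in kmers if km in index) / len(kmers)
    return CompartmentCall(unigene.id, containment, containment >= threshold, "kmer")


def classify_many(
    unigenes: list[SeqRecord], index: set[str], k: int = 21, threshold: float = 0.5
) -> list[CompartmentCall]:
    return [classify_compartment(u, index, k, threshold) for u in unigenes]


def import_hits(table: str | Path, evalue_cutoff: float = 1e-50) -> list[CompartmentCall]:
    """Compartment calls from a 12-column tabular similarity-hit file.

    A unigene is chloroplast iff any of its hits passes the e-value cutoff.
    Unigenes appear in first-occurrence order.
    """
    try:
        df = pd.read_csv(table, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise FormatError(f"{table}: expected 12 tab-separated columns, found {df.shape[1]}")
    df.columns = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    if not pd.api.types.is_numeric_dtype(df["evalue"]):
        raise FormatError(f"{table}: non-numeric e-value column")
    calls: list[CompartmentCall] = []
    for qid, grp in df.groupby("query", sort=False):
        hit = bool((grp["evalue"] <= evalue_cutoff).any())
        calls.append(CompartmentCall(str(qid), None, hit, "imported"))
    return calls
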