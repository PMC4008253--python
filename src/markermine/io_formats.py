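"""Readers and writers for the plain-text formats the marker pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython and SAM parsing to pysam; this
module layers the strict validation the downstream scanners rely on (a
five-letter A/C/G/T/N alphabet, unique record ids, a minimal M/I/D/S CIGAR
dialect) and normalises every coordinate to 0-based half-open. Reported
tables, in contrast, use 1-based inclusive coordinates — the convention of
the marker sheets this pipeline emits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

VALID_RESIDUES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated the format contract (malformed record, bad alphabet...)."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence, optionally with per-base Phred qualities."""

    id: str
    residues: str
    description: str = ""
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id {self.id!r} is empty or contains whitespace")
        if len(self.residues) == 0:
            raise FormatError(f"record {self.id!r}: empty sequence")
        self.residues = self.residues.upper()
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)!r}; "
                "allowed alphabet is A,C,G,T,N"
            )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise FormatError(
                f"record {self.id!r}: {len(self.qualities)} qualities for "
                f"{len(self.residues)} residues"
            )

    def __len__(self) -> int:
        return len(self.residues)


#: CIGAR operations accepted on input. S is clipped off the read on ingest and
#: never stored; alignments in memory use only M, I, D.
SAM_OPS = {0: "M", 1: "I", 2: "D", 4: "S"}


@dataclass
class AlignmentRecord:
    """A read placed on a reference transcript.

    ``read_seq`` is stored in reference orientation (already reverse
    complemented for minus-strand reads, as in SAM). ``cigar`` is an ordered
    list of ``(length, op)`` with op in {M, I, D}.
    """

    read_id: str
    ref_id: str
    ref_start: int
    strand: str
    cigar: list[tuple[int, str]]
    read_seq: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise FormatError(f"read {self.read_id!r}: strand must be + or -")
        if self.ref_start < 0:
            raise FormatError(f"read {self.read_id!r}: negative reference start")
        ops = {op for _, op in self.cigar}
        if not ops <= {"M", "I", "D"}:
            raise FormatError(f"read {self.read_id!r}: unsupported CIGAR ops {ops - {'M', 'I', 'D'}}")
        if self.read_span != len(self.read_seq):
            raise FormatError(
                f"read {self.read_id!r}: CIGAR read span {self.read_span} != "
                f"sequence length {len(self.read_seq)}"
            )

    @property
    def read_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MI")

    @property
    def ref_span(self) -> int:
        return sum(n for n, op in self.cigar if op in "MD")

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.ref_span


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _ingest_biopython(records, path, with_quals: bool) -> list[SeqRecord]:
    out: list[SeqRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r} (record {i})")
        seen.add(rec.id)
        quals = rec.letter_annotations.get("phred_quality") if with_quals else None
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        try:
            out.append(SeqRecord(rec.id, str(rec.seq), desc, list(quals) if quals is not None else None))
        except FormatError as exc:
            raise FormatError(f"{path}: record {i}: {exc}") from exc
    return out


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(1)
        if head != ">":
            raise FormatError(f"{path}: not a FASTA file (first character {head!r}, expected '>')")
    return _ingest_biopython(SeqIO.parse(path, "fasta"), path, with_quals=False)


def read_fastq(path: str | Path) -> list[SeqRecord]:
    """Read a Phred+33 FASTQ file into validated :class:`SeqRecord` objects."""
    path = Path(path)
    return _ingest_biopython(SeqIO.parse(path, "fastq"), path, with_quals=True)


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(f"{header}\n{rec.residues}\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qualities is None:
                raise FormatError(f"record {rec.id!r}: FASTQ output requires qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            fh.write(f"@{rec.id}\n{rec.residues}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM (minimal transcript-space dialect)


def read_sam(path: str | Path, refs: Mapping[str, int]) -> list[AlignmentRecord]:
    """Read a SAM file of read-to-transcript alignments.

    ``refs`` maps reference id to length and is checked against the @SQ
    header. Unmapped records are skipped; soft clips are removed from the
    stored read sequence; CIGAR ops outside M/I/D/S are rejected.
    """
    path = Path(path)
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for sq in sam.header.get("SQ", []):
            name, length = sq["SN"], sq["LN"]
            if name in refs and refs[name] != length:
                raise FormatError(
                    f"{path}: @SQ length {length} for {name!r} disagrees with "
                    f"expected {refs[name]}"
                )
        for rec in sam:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in refs:
                raise FormatError(f"{path}: read {rec.query_name!r} maps to unknown reference {rec.reference_name!r}")
            if rec.cigartuples is None or rec.query_sequence is None:
                raise FormatError(f"{path}: read {rec.query_name!r}: missing CIGAR or sequence")
            seq = rec.query_sequence.upper()
            cigar: list[tuple[int, str]] = []
            lo, hi = 0, len(seq)
            for i, (op_code, n) in enumerate(rec.cigartuples):
                op = SAM_OPS.get(op_code)
                if op is None:
                    raise FormatError(
                        f"{path}: read {rec.query_name!r}: unsupported CIGAR op code {op_code}"
                    )
                if op == "S":
                    if i == 0:
                        lo = n
                    else:
                        hi -= n
                else:
                    cigar.append((n, op))
            aln = AlignmentRecord(
                read_id=rec.query_name,
                ref_id=rec.reference_name,
                ref_start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar,
                read_seq=seq[lo:hi],
            )
            if aln.ref_end > refs[aln.ref_id]:
                raise FormatError(
                    f"{path}: read {rec.query_name!r}: alignment [{aln.ref_start},"
                    f"{aln.ref_end}) exceeds reference {aln.ref_id!r} length {refs[aln.ref_id]}"
                )
            out.append(aln)
    return out


def write_sam(alignments: Iterable[AlignmentRecord], refs: Mapping[str, int], path: str | Path) -> None:
    """Write alignments as plain-text SAM with an @SQ header per reference."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in refs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln in alignments:
            flag = 16 if aln.strand == "-" else 0
            cigar = "".join(f"{n}{op}" for n, op in aln.cigar)
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.ref_id}\t{aln.ref_start + 1}\t60\t"
                f"{cigar}\t*\t0\t0\t{aln.read_seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# Result tables


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write uniform records as a TSV with a deterministic column order.

    ``rows`` may be a DataFrame or a sequence of mappings sharing a schema;
    an empty sequence with explicit ``columns`` yields a header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        if columns is None:
            columns = list(rows[0].keys()) if rows else []
        for i, row in enumerate(rows):
            if list(row.keys()) != list(columns):
                raise FormatError(f"row {i} schema {list(row.keys())} differs from {list(columns)}")
        df = pd.DataFrame(rows, columns=list(columns))
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
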