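"""Sequence records and FASTA/FASTQ input/output.

Everything downstream (panel generation, sketching, clustering, read
simulation, evaluation) moves sequences around as :class:`SequenceRecord`.
Parsing is strict by design: malformed records raise :class:`ParseError`
naming the offending line, nucleotide sequences are validated against
``{A,C,G,T,N}``, and qualities are Phred+33 integers in [0, 60].
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY*X")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Raised when a sequence file is malformed; the message names the line."""


@dataclass
class SequenceRecord:
    """One nucleotide or protein sequence.

    Parameters
    ----------
    id:
        Unique identifier; non-empty, no whitespace.
    seq:
        Upper-case sequence string.
    description:
        Free text after the identifier on the header line.
    qual:
        Optional per-base Phred scores (ints in [0, 60]), same length as
        ``seq``. Present iff the record came from (or is destined for) FASTQ.
    """

    id: str
    seq: str
    description: str = ""
    qual: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid record id: {self.id!r}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id}: qual length {len(self.qual)} != "
                f"seq length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_sequences(path, format: str | None = None) -> list[SequenceRecord]:
    """Parse a FASTA or FASTQ file into a list of records, preserving order.

    ``format`` is ``"fasta"`` or ``"fastq"``; if ``None`` it is inferred from
    the filename (``.fq``/``.fastq`` -> fastq, else fasta). FASTA line
    wrapping is collapsed; FASTQ qualities are decoded as Phred+33.

    Raises
    ------
    ParseError
        On a missing header, a truncated record, or a seq/qual length
        mismatch; the message names the line number.
    """
    path = Path(path)
    if format is None:
        stem = path.name[:-3] if path.name.endswith(".gz") else path.name
        format = "fastq" if stem.endswith((".fq", ".fastq")) else "fasta"
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    with _open(path) as fh:
        lines = fh.read().splitlines()
    if format == "fasta":
        return _parse_fasta(lines)
    return _parse_fastq(lines)


def _split_header(header: str) -> tuple[str, str]:
    parts = header.split(maxsplit=1)
    return parts[0], parts[1] if len(parts) > 1 else ""


def _parse_fasta(lines: list[str]) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        rid, desc = _split_header(header)
        if not rid:
            raise ParseError(f"line {header_line}: empty FASTA header")
        records.append(SequenceRecord(rid, "".join(chunks).upper(), desc))

    for i, line in enumerate(lines, 1):
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            header_line = i
            chunks = []
        else:
            if header is None:
                raise ParseError(f"line {i}: sequence data before any header")
            chunks.append(line.strip())
    flush()
    return records


def _parse_fastq(lines: list[str]) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) % 4 != 0:
        raise ParseError(
            f"line {len(lines)}: truncated FASTQ record (file has "
            f"{len(lines)} non-empty lines, not a multiple of 4)"
        )
    for i in range(0, len(lines), 4):
        lineno = i + 1
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise ParseError(f"line {lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise ParseError(f"line {lineno + 2}: expected '+' separator")
        if len(seq) != len(qual):
            raise ParseError(
                f"line {lineno + 3}: quality length {len(qual)} != "
                f"sequence length {len(seq)}"
            )
        rid, desc = _split_header(head[1:].strip())
        if not rid:
            raise ParseError(f"line {lineno}: empty FASTQ header")
        quals = [ord(c) - 33 for c in qual]
        bad = [q for q in quals if q < 0 or q > 60]
        if bad:
            raise ParseError(f"line {lineno + 3}: Phred score {bad[0]} outside [0, 60]")
        records.append(SequenceRecord(rid, seq.upper(), desc, quals))
    return records


def write_sequences(
    records: Iterable[SequenceRecord],
    path,
    format: str = "fasta",
    wrap: int | None = 80,
) -> None:
    """Write records as FASTA (wrapped at ``wrap`` columns) or FASTQ (Phred+33).

    Output is byte-deterministic for fixed input. Writing a record without
    qualities as FASTQ is an error.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    if wrap is not None and wrap < 1:
        raise ValueError("wrap must be >= 1 or None")
    with _open(path, "wt") as fh:
        for rec in records:
            header = f"{rec.id} {rec.description}".rstrip()
            if format == "fasta":
                fh.write(f">{header}\n")
                if wrap is None:
                    fh.write(rec.seq + "\n")
                else:
                    for i in range(0, len(rec.seq), wrap):
                        fh.write(rec.seq[i : i + wrap] + "\n")
            else:
                if rec.qual is None:
                    raise ValueError(
                        f"record {rec.id} has no qualities; cannot write FASTQ"
                    )
                qline = "".join(chr(q + 33) for q in rec.qual)
                fh.write(f"@{header}\n{rec.seq}\n+\n{qline}\n")


def check_nucleotide(seq: str) -> str:
    """Validate that ``seq`` is over {A,C,G,T,N}; return it unchanged."""
    bad = set(seq) - NUCLEOTIDES
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return seq


def gc_fraction(seq: str) -> float:
    """Fraction (#G + #C) / (#A + #C + #G + #T); N excluded from both sides.

    Raises on an empty or all-N sequence.
    """
    check_nucleotide(seq)
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("gc_fraction undefined for empty or all-N sequence")
    return gc / denom


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    check_nucleotide(seq)
    return seq.translate(_COMPLEMENT)[::-1]
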