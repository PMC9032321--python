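"""Readers and writers for the plain-text formats the pipeline touches.

Four formats are handled: FASTA and four-line FASTQ (parsed with Biopython's
low-level iterators), the de-facto 12-column tabular alignment layout emitted
by BLAST-family tools with ``-outfmt 6`` (``qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore``) optionally
extended with a 13th subject-category column, and simple TSV report tables.

Residues are uppercased on ingest. Characters outside {A, C, G, T, N} —
IUPAC ambiguity codes, U, etc. — are mapped to N with a logged warning,
because downstream exact matching treats N as never-matching. Coordinates in
:class:`TabularHit` stay 1-based inclusive as in the source format; every
other coordinate in this package is 0-based half-open.
"""

from __future__ import annotations

import gzip
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Categories a comprehensive-search subject may carry (13th tabular column).
SUBJECT_CATEGORIES = ("viral", "cellular", "unknown")


def reverse_complement(residues: str) -> str:
    """Reverse-complement a DNA string over the ACGTN alphabet."""
    return residues.translate(_COMPLEMENT)[::-1]


def _sanitize_residues(raw: str, context: str) -> str:
    """Uppercase and coerce to the ACGTN alphabet (other letters -> N)."""
    seq = raw.upper()
    if not set(seq) <= _ALPHABET:
        bad = sorted(set(seq) - _ALPHABET)
        for ch in bad:
            if not ch.isalpha():
                raise ParseError(
                    f"{context}: illegal residue character {ch!r}"
                )
        logger.warning(
            "%s: mapped non-ACGTN residue(s) %s to N", context, ",".join(bad)
        )
        seq = "".join(c if c in _ALPHABET else "N" for c in seq)
    return seq


@dataclass
class SequenceRecord:
    """An identified nucleotide sequence (assembled contig or viral genome)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a whitespace-free token: {self.id!r}")
        if not self.residues:
            raise ValueError(f"record {self.id}: residues must be non-empty")
        self.residues = _sanitize_residues(self.residues, f"record {self.id}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadRecord:
    """One small-RNA read, optionally with its verbatim quality string."""

    id: str
    residues: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"read {self.id}: empty sequence")
        self.residues = _sanitize_residues(self.residues, f"read {self.id}")
        if self.quality is not None and len(self.quality) != len(self.residues):
            raise ParseError(
                f"read {self.id}: sequence length {len(self.residues)} != "
                f"quality length {len(self.quality)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TabularHit:
    """One homology-search alignment row (outfmt-6 layout + category)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_category: str = "unknown"

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: negative evalue")
        if self.q_start > self.q_end:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: q_start > q_end")
        if not math.isfinite(self.bitscore):
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: non-finite bitscore")
        if self.subject_category not in SUBJECT_CATEGORIES:
            raise ValueError(
                f"hit {self.query_id}/{self.subject_id}: unknown subject "
                f"category {self.subject_category!r}"
            )


def _open_text(path: str | Path) -> io.TextIOBase:
    """Open plain or gzipped text with universal newlines (CRLF tolerated)."""
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8", newline=None)
    return open(path, "r", encoding="utf-8", newline=None)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into :class:`SequenceRecord` objects.

    The id is the header text up to the first whitespace; the remainder is
    kept as the description. Multi-line sequences are concatenated and
    uppercased. Raises :class:`ParseError` for an empty file, leading
    non-header text, or duplicate ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}: sequence line before any FASTA header")
                break
        handle.seek(0)
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(None, 1)
            if not parts:
                raise ParseError(f"{path}: FASTA header with empty id")
            rec_id = parts[0]
            desc = parts[1] if len(parts) > 1 else ""
            if rec_id in seen:
                raise ParseError(f"{path}: duplicate record id {rec_id!r}")
            seen.add(rec_id)
            records.append(SequenceRecord(id=rec_id, residues=seq, description=desc))
    if not records:
        raise ParseError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Parse four-line FASTQ into :class:`ReadRecord` objects.

    Quality strings are retained verbatim; residues are uppercased. A
    truncated final record or a sequence/quality length mismatch raises
    :class:`ParseError` naming the offending record where possible.
    """
    reads: list[ReadRecord] = []
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                rec_id = title.split(None, 1)[0]
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: read {rec_id}: sequence/quality length mismatch"
                    )
                reads.append(ReadRecord(id=rec_id, residues=seq, quality=qual))
        except ValueError as exc:  # Biopython's own malformed-FASTQ errors
            raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as four-line FASTQ (missing qualities become 'I')."""
    with open(path, "w", encoding="utf-8") as handle:
        for read in reads:
            qual = read.quality if read.quality is not None else "I" * len(read.residues)
            handle.write(f"@{read.id}\n{read.residues}\n+\n{qual}\n")


def read_fasta_or_fastq_reads(path: str | Path) -> list[ReadRecord]:
    """Load sRNA reads from either FASTA or FASTQ, sniffing the first byte."""
    with _open_text(path) as handle:
        first = handle.read(1)
    if first == ">":
        return [
            ReadRecord(id=r.id, residues=r.residues) for r in read_fasta(path)
        ]
    return read_fastq(path)


_TABULAR_COLUMNS = (
    "query_id subject_id percent_identity aln_length mismatches gap_opens "
    "q_start q_end s_start s_end evalue bitscore"
).split()


def read_tabular_hits(path: str | Path) -> list[TabularHit]:
    """Parse 12- or 13-column tab-separated alignment rows.

    Numeric fields accept scientific notation. Rows with only 12 columns get
    ``subject_category='unknown'``. Malformed rows raise :class:`ParseError`
    carrying the 1-based line number.
    """
    hits: list[TabularHit] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ParseError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated "
                    f"columns, found {len(fields)}"
                )
            try:
                hit = TabularHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    subject_category=fields[12] if len(fields) == 13 else "unknown",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_tabular_hits(hits: Iterable[TabularHit], path: str | Path) -> None:
    """Write hits in the 13-column tabular layout (category always emitted)."""
    with open(path, "w", encoding="utf-8") as handle:
        for h in hits:
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _fmt_number(h.percent_identity),
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt_number(h.evalue),
                        _fmt_number(h.bitscore),
                        h.subject_category,
                    ]
                )
                + "\n"
            )


def _fmt_number(value: object) -> str:
    """Render numbers at 6 significant digits; everything else via str()."""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a list of homogeneous row dicts as a TSV report.

    The column order is taken from ``columns`` or from the first row. Rows
    with a different key set raise ``ValueError``. Floats are rendered at 6
    significant digits; NaN renders as ``NA``.
    """
    if columns is None:
        if not rows:
            raise ValueError("empty table requires an explicit column list")
        columns = list(rows[0].keys())
    colset = set(columns)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(columns) + "\n")
        for i, row in enumerate(rows):
            if set(row.keys()) != colset:
                raise ValueError(
                    f"row {i} columns {sorted(row)} do not match header {sorted(colset)}"
                )
            handle.write("\t".join(_fmt_number(row[c]) for c in columns) + "\n")


def read_tsv(path: str | Path) -> "pandas.DataFrame":  # noqa: F821
    """Read a TSV report back into a DataFrame ('NA' parsed as missing)."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
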