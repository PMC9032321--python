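"""Small-RNA preprocessing and zero-mismatch mapping.

The preprocessing steps are the standard sRNA-seq ones: size selection
(18–30 nt by default, the window in which siRNA products fall), dropping of
N-containing reads, and collapsing of identical reads into (sequence,
count) pairs. Mapping is exact: a read is placed wherever its sequence (or
its reverse complement) occurs verbatim in the genome, with every
occurrence reported — multi-mapped reads yield one record per site, and
downstream counting weights each site by the read's collapse count.

The index is a hash of fixed-length seeds (the minimum read length) into
genome positions; a candidate position is then verified against the full
query so lookups are exact at any length in the indexed range. Genome
positions containing N never match.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from .seqio import ReadRecord, SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "CollapsedRead",
    "MappingRecord",
    "extract_by_length",
    "collapse",
    "SubstringIndex",
    "build_index",
    "map_exact",
]

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct read sequence and how many identical raw reads carried it."""

    residues: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if "N" in self.residues:
            raise ValueError("collapsed reads may not contain N")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MappingRecord:
    """One exact placement of a collapsed read on a genome strand.

    ``left`` is the 0-based leftmost genome offset of the matched span.
    ``five_prime_pos`` is the genome offset of the read's 5' nucleotide:
    equal to ``left`` for sense placements and to ``left + len - 1`` for
    antisense placements (the read's 5' end faces the other way).
    """

    read: CollapsedRead
    genome_id: str
    left: int
    strand: str
    five_prime_pos: int

    def __post_init__(self) -> None:
        if self.strand not in (SENSE, ANTISENSE):
            raise ValueError(f"unknown strand {self.strand!r}")
        expected = self.left if self.strand == SENSE else self.left + len(self.read) - 1
        if self.five_prime_pos != expected:
            raise ValueError(
                f"five_prime_pos {self.five_prime_pos} inconsistent with "
                f"left={self.left}, strand={self.strand}, len={len(self.read)}"
            )


def extract_by_length(
    reads: list[ReadRecord], min_len: int = 18, max_len: int = 30
) -> list[ReadRecord]:
    """Keep reads whose length lies in [min_len, max_len], order preserved."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse(reads: list[ReadRecord]) -> list[CollapsedRead]:
    """Deduplicate reads into (sequence, count) pairs.

    Reads containing N are dropped before collapsing (exact matching with N
    is undefined); the dropped tally is logged. Output is sorted by
    descending count, then lexicographic sequence, and its counts sum to the
    number of N-free input reads.
    """
    dropped = 0
    tally: Counter[str] = Counter()
    for r in reads:
        if "N" in r.residues:
            dropped += 1
        else:
            tally[r.residues] += 1
    if dropped:
        logger.info("collapse: dropped %d read(s) containing N", dropped)
    collapsed = [CollapsedRead(residues=s, count=c) for s, c in tally.items()]
    collapsed.sort(key=lambda cr: (-cr.count, cr.residues))
    return collapsed


class SubstringIndex:
    """Exact-occurrence index over one genome for queries of bounded length.

    Seeds of length ``min_len`` are hashed to their genome positions; a
    lookup fetches the candidate positions of the query's seed prefix and
    verifies the full-length substring, so each reported occurrence costs
    O(query length) regardless of genome size.
    """

    def __init__(self, genome: SequenceRecord, min_len: int = 18, max_len: int = 30):
        if min_len < 1 or min_len > max_len:
            raise ValueError("require 1 <= min_len <= max_len")
        if len(genome) < min_len:
            raise ValueError(
                f"genome {genome.id} ({len(genome)} nt) shorter than min_len {min_len}"
            )
        self.genome_id = genome.id
        self.min_len = min_len
        self.max_len = max_len
        self._seq = genome.residues
        self._seeds: dict[str, list[int]] = {}
        k = min_len
        seq = self._seq
        for pos in range(len(seq) - k + 1):
            seed = seq[pos : pos + k]
            if "N" in seed:
                continue
            self._seeds.setdefault(seed, []).append(pos)

    @property
    def genome_length(self) -> int:
        return len(self._seq)

    def _occurrences(self, query: str) -> list[int]:
        positions = []
        for pos in self._seeds.get(query[: self.min_len], ()):
            if self._seq[pos : pos + len(query)] == query:
                positions.append(pos)
        return positions

    def lookup(self, query: str) -> list[tuple[int, str]]:
        """All exact occurrences of ``query`` as (left, strand) pairs.

        Queries outside the indexed length range are rejected with
        ``ValueError``; queries containing N match nowhere.
        """
        if not self.min_len <= len(query) <= self.max_len:
            raise ValueError(
                f"query length {len(query)} outside indexed range "
                f"[{self.min_len}, {self.max_len}]"
            )
        if "N" in query:
            return []
        hits = [(pos, SENSE) for pos in self._occurrences(query)]
        rc = reverse_complement(query)
        hits += [(pos, ANTISENSE) for pos in self._occurrences(rc)]
        return hits


def build_index(
    genome: SequenceRecord, min_len: int = 18, max_len: int = 30
) -> SubstringIndex:
    """Construct a :class:`SubstringIndex` over ``genome``."""
    return SubstringIndex(genome, min_len=min_len, max_len=max_len)


def map_exact(reads: list[CollapsedRead], index: SubstringIndex) -> list[MappingRecord]:
    """Place every collapsed read at all of its exact genome occurrences.

    Reads matching neither strand yield no records. Output is sorted by
    (left, strand, sequence) for deterministic reports.
    """
    records: list[MappingRecord] = []
    for read in reads:
        for left, strand in index.lookup(read.residues):
            fp = left if strand == SENSE else left + len(read) - 1
            records.append(
                MappingRecord(
                    read=read,
                    genome_id=index.genome_id,
                    left=left,
                    strand=strand,
                    five_prime_pos=fp,
                )
            )
    records.sort(key=lambda m: (m.left, m.strand, m.read.residues))
    return records


def mapping_rows(records: list[MappingRecord]) -> list[dict]:
    """Flatten mapping records into report rows (1-based coordinates)."""
    return [
        {
            "read": m.read.residues,
            "count": m.read.count,
            "genome_id": m.genome_id,
            "left_1based": m.left + 1,
            "strand": m.strand,
            "five_prime_pos_1based": m.five_prime_pos + 1,
        }
        for m in records
    ]


def records_from_rows(rows, genome_id: str | None = None) -> list[MappingRecord]:
    """Rebuild :class:`MappingRecord` objects from mapping-report rows.

    Accepts any iterable of dict-like rows with the columns written by
    :func:`mapping_rows` (e.g. a DataFrame's ``to_dict('records')``).
    """
    records = []
    for row in rows:
        residues = str(row["read"])
        strand = str(row["strand"])
        left = int(row["left_1based"]) - 1
        fp = left if strand == SENSE else left + len(residues) - 1
        records.append(
            MappingRecord(
                read=CollapsedRead(residues=residues, count=int(row["count"])),
                genome_id=genome_id or str(row["genome_id"]),
                left=left,
                strand=strand,
                five_prime_pos=fp,
            )
        )
    return records
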