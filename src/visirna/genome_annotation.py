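"""ORF prediction, translation, UTR segmentation and overlap detection.

The genome architectures this module targets are those of positive-sense
RNA viruses of insects: a single long polyprotein ORF flanked by short UTRs
(iflavirus-like), or several ORFs of which one pair overlaps in different
reading frames (nido-like). An ORF here is an ATG-initiated, stop-terminated
maximal span in a fixed frame and strand; nested ATGs sharing a stop are
suppressed (longest-per-stop). Coordinates are 0-based half-open internally;
report files emit 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .errors import TranslationError
from .seqio import SequenceRecord, reverse_complement

__all__ = [
    "OrfAnnotation",
    "GenomeAnnotation",
    "find_orfs",
    "translate",
    "segment_genome",
    "detect_overlaps",
]

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_TO_AA = dict(_STANDARD.forward_table)
_STOP_CODONS = frozenset(_STANDARD.stop_codons)
START_CODON = "ATG"


@dataclass
class OrfAnnotation:
    """One predicted open reading frame.

    ``start``/``end`` are 0-based half-open genome offsets of the full span
    including the terminal stop codon, so ``(end - start) / 3 - 1`` equals
    the protein length. ``frame`` is the span's offset modulo 3 relative to
    the 5' end of its own strand.
    """

    start: int
    end: int
    strand: str
    frame: int
    protein: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be divisible by 3")
        if (self.end - self.start) // 3 - 1 != len(self.protein):
            raise ValueError("protein length inconsistent with ORF span")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """Per-genome ORF list plus derived UTR segmentation and overlaps."""

    genome_id: str
    genome_length: int
    orfs: list[OrfAnnotation]
    utr5_length: int
    utr3_length: int
    overlaps: list[tuple[int, int, int]] = field(default_factory=list)


def translate(cds: str) -> str:
    """Translate a coding nucleotide sequence with the standard code.

    The terminal stop codon, if present, is dropped. Codons containing N
    translate to 'X' (ambiguous assembly positions are tolerated). An
    internal stop raises :class:`TranslationError` naming the codon index,
    as does a length not divisible by 3.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise TranslationError(
            f"CDS length {len(cds)} nt is not divisible by 3"
        )
    n_codons = len(cds) // 3
    protein: list[str] = []
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3]
        if codon in _STOP_CODONS:
            if i == n_codons - 1:
                break  # terminal stop: encoded but not translated
            raise TranslationError(f"internal stop codon {codon} at codon index {i}")
        if "N" in codon:
            protein.append("X")
        else:
            try:
                protein.append(_CODON_TO_AA[codon])
            except KeyError as exc:
                raise TranslationError(f"unrecognized codon {codon!r} at index {i}") from exc
    return "".join(protein)


def _scan_strand(seq: str, min_protein_len: int) -> list[tuple[int, int, int]]:
    """Yield (start, end, frame) ORF spans in the coordinates of ``seq``.

    Longest-per-stop: within each stop-delimited run, only the first ATG
    is reported. ORFs running off the end without a stop are not reported.
    """
    spans: list[tuple[int, int, int]] = []
    n = len(seq)
    for frame in range(3):
        atg: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in _STOP_CODONS:
                if atg is not None:
                    end = pos + 3
                    if (end - atg) // 3 - 1 >= min_protein_len:
                        spans.append((atg, end, frame))
                    atg = None
            elif atg is None and codon == START_CODON:
                atg = pos
    return spans


def find_orfs(
    genome: SequenceRecord,
    min_protein_len: int = 100,
    strands: tuple[str, ...] = ("+",),
) -> list[OrfAnnotation]:
    """Predict ORFs on the requested strands, sorted by genome start.

    Defaults suit positive-sense RNA virus genomes: plus strand only,
    proteins of at least 100 aa. Genomes shorter than 6 nt yield an empty
    list (no room for start + stop).
    """
    if min_protein_len < 1:
        raise ValueError("min_protein_len must be >= 1")
    for s in strands:
        if s not in ("+", "-"):
            raise ValueError(f"unknown strand {s!r}")
    seq = genome.residues
    n = len(seq)
    if n < 6:
        return []
    orfs: list[OrfAnnotation] = []
    if "+" in strands:
        for start, end, frame in _scan_strand(seq, min_protein_len):
            orfs.append(
                OrfAnnotation(
                    start=start,
                    end=end,
                    strand="+",
                    frame=frame,
                    protein=translate(seq[start:end]),
                )
            )
    if "-" in strands:
        rc = reverse_complement(seq)
        for start, end, frame in _scan_strand(rc, min_protein_len):
            # mirror scanned coordinates back onto the plus-strand axis
            orfs.append(
                OrfAnnotation(
                    start=n - end,
                    end=n - start,
                    strand="-",
                    frame=frame,
                    protein=translate(rc[start:end]),
                )
            )
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def detect_overlaps(orfs: list[OrfAnnotation]) -> list[tuple[int, int, int]]:
    """Report all ORF index pairs with a positive interval intersection.

    Returns ``(i, j, overlap_nt)`` tuples with ``i < j`` indexing the input
    list (which must be sorted by start). Touching half-open intervals do
    not overlap.
    """
    out: list[tuple[int, int, int]] = []
    for i in range(len(orfs)):
        for j in range(i + 1, len(orfs)):
            ov = min(orfs[i].end, orfs[j].end) - max(orfs[i].start, orfs[j].start)
            if ov > 0:
                out.append((i, j, ov))
    return out


def segment_genome(
    genome_length: int,
    orfs: list[OrfAnnotation],
    genome_id: str = "genome",
) -> GenomeAnnotation:
    """Derive UTR lengths (and overlaps) from a genome's ORF set.

    The 5' UTR is everything upstream of the first plus-strand ORF; the 3'
    UTR everything downstream of the last. For a single-ORF genome,
    ``utr5 + orf_span + utr3 == genome_length``.
    """
    for o in orfs:
        if o.start < 0 or o.end > genome_length:
            raise ValueError(
                f"ORF [{o.start}, {o.end}) exceeds genome bounds 0..{genome_length}"
            )
    plus = [o for o in orfs if o.strand == "+"]
    if not plus:
        raise ValueError("segmentation requires at least one plus-strand ORF")
    utr5 = min(o.start for o in plus)
    utr3 = genome_length - max(o.end for o in plus)
    return GenomeAnnotation(
        genome_id=genome_id,
        genome_length=genome_length,
        orfs=sorted(orfs, key=lambda o: (o.start, o.end)),
        utr5_length=utr5,
        utr3_length=utr3,
        overlaps=detect_overlaps(sorted(orfs, key=lambda o: (o.start, o.end))),
    )


def annotation_rows(annotation: GenomeAnnotation) -> list[dict]:
    """Flatten an annotation into GFF3-like report rows (1-based inclusive)."""
    rows: list[dict] = []
    if annotation.utr5_length > 0:
        rows.append(
            {
                "seqid": annotation.genome_id,
                "source": "visirna",
                "type": "five_prime_UTR",
                "start": 1,
                "end": annotation.utr5_length,
                "strand": "+",
            }
        )
    for o in annotation.orfs:
        rows.append(
            {
                "seqid": annotation.genome_id,
                "source": "visirna",
                "type": "CDS",
                "start": o.start + 1,
                "end": o.end,
                "strand": o.strand,
            }
        )
    if annotation.utr3_length > 0:
        rows.append(
            {
                "seqid": annotation.genome_id,
                "source": "visirna",
                "type": "three_prime_UTR",
                "start": annotation.genome_length - annotation.utr3_length + 1,
                "end": annotation.genome_length,
                "strand": "+",
            }
        )
    return rows
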