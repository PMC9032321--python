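"""Ground-truth generators for genomes, sRNA libraries and triage fixtures.

Every other module is exercised against data produced here, so each
generator returns its ground truth alongside the data and is
bit-reproducible for a fixed (spec, seed) pair.

*Genomes* are random sequences at a chosen GC content with ORFs planted at
exact coordinates: start/stop codons are anchored, ORF bodies are kept free
of in-frame stops, an in-frame stop is placed immediately upstream of each
planted start where possible, and a bounded repair loop removes any
spurious ORF at or above the shortest planted protein length so that ORF
prediction recovers exactly the planted layout. Two presets mirror common
insect-virus architectures: a single long polyprotein ORF flanked by short
UTRs (iflavirus-like) and four ORFs with one overlapping pair in different
frames (nido-like).

*Libraries* emulate the small-RNA signature of an active antiviral RNAi
response: read lengths from a size distribution peaking at 21 nt, strands
drawn near-equally, a 5'-terminal base bias imposed at the 21-nt analysis
length by conditional sampling of start positions, positional hotspots via
rate multipliers, and an optional background of host reads verified never
to match the genome.

*Triage fixtures* emulate a candidate-contig table in which nearly all
contigs best-match host proteins in the comprehensive search despite
passing the viral-homology screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SyntheticDataError
from .genome_annotation import (
    GenomeAnnotation,
    detect_overlaps,
    find_orfs,
    segment_genome,
)
from .seqio import ReadRecord, SequenceRecord, TabularHit, reverse_complement
from .srna_mapping import ANTISENSE, SENSE

__all__ = [
    "GenomeSpec",
    "LibrarySpec",
    "TriageFixture",
    "generate_genome",
    "generate_library",
    "generate_triage_fixture",
    "iflavirus_like_genome_spec",
    "nido_like_genome_spec",
    "default_library_spec",
]

_STOPS = ("TAA", "TAG", "TGA")
_BASES = ("A", "C", "G", "T")
_RNA_TO_DNA = {"A": "A", "C": "C", "G": "G", "U": "T"}

#: Read-length window of the siRNA size selection.
MIN_SRNA_LEN, MAX_SRNA_LEN = 18, 30

#: Default size distribution: sharp Dicer-product peak at 21 nt.
DEFAULT_SIZE_PROBS = {
    18: 0.02, 19: 0.03, 20: 0.10, 21: 0.60, 22: 0.12, 23: 0.04, 24: 0.02,
    25: 0.02, 26: 0.015, 27: 0.015, 28: 0.01, 29: 0.005, 30: 0.005,
}

#: Default 5'-terminal base bias at the analysis length (strong A/U bias).
DEFAULT_FIVE_PRIME_PROBS = {"U": 0.40, "A": 0.35, "C": 0.15, "G": 0.10}


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Layout of a synthetic viral genome with planted ORFs."""

    length: int
    gc: float = 0.42
    orf_layout: list[tuple[int, int, str]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("genome length must be positive")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        for start, end, strand in self.orf_layout:
            if strand not in ("+", "-"):
                raise SyntheticDataError(f"unknown strand {strand!r}")
            if not (0 <= start < end <= self.length):
                raise SyntheticDataError(
                    f"planted ORF [{start}, {end}) outside genome of length {self.length}"
                )
            if (end - start) % 3 != 0:
                raise SyntheticDataError(
                    f"planted ORF [{start}, {end}) span not divisible by 3"
                )
            if end - start < 9:
                raise SyntheticDataError("planted ORFs need >= 3 codons")


def iflavirus_like_genome_spec(seed: int = 0) -> GenomeSpec:
    """Single-ORF architecture: 9716 nt = 181 nt 5'UTR + 9297 nt ORF + 238 nt 3'UTR."""
    return GenomeSpec(length=9716, gc=0.40, orf_layout=[(181, 9478, "+")], seed=seed)


def nido_like_genome_spec(seed: int = 0) -> GenomeSpec:
    """Four-ORF architecture on 20,193 nt with a 76 nt 5'UTR, a 1046 nt
    3'UTR, and exactly one overlapping ORF pair (the last two, in
    different frames) — the hallmark layout of nido-like genomes."""
    return GenomeSpec(
        length=20193,
        gc=0.45,
        orf_layout=[
            (76, 12076, "+"),
            (12100, 16099, "+"),
            (16151, 18149, "+"),
            (18127, 19147, "+"),
        ],
        seed=seed,
    )


def _codon_block(pos: int, start: int, end: int, strand: str) -> int:
    """Leftmost genome offset of the codon of ``pos`` within an ORF."""
    if strand == "+":
        return pos - (pos - start) % 3
    return end - 3 * ((end - 1 - pos) // 3 + 1)


def _block_codon(seq: list[str], block: int, strand: str) -> str:
    codon = "".join(seq[block : block + 3])
    return codon if strand == "+" else reverse_complement(codon)


class _GenomeBuilder:
    def __init__(self, spec: GenomeSpec, genome_id: str):
        self.spec = spec
        self.genome_id = genome_id
        self.rng = np.random.default_rng(spec.seed)
        self.layout = sorted(spec.orf_layout)
        self._check_frames()
        probs = [
            (1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2
        ]
        self.seq = list(self.rng.choice(_BASES, size=spec.length, p=probs))
        self.anchors: set[int] = set()

    def _check_frames(self) -> None:
        for i in range(len(self.layout)):
            for j in range(i + 1, len(self.layout)):
                s1, e1, st1 = self.layout[i]
                s2, e2, st2 = self.layout[j]
                if min(e1, e2) - max(s1, s2) <= 0 or st1 != st2:
                    continue
                same_frame = (
                    s1 % 3 == s2 % 3 if st1 == "+" else e1 % 3 == e2 % 3
                )
                if same_frame:
                    raise SyntheticDataError(
                        f"ORFs [{s1},{e1}) and [{s2},{e2}) overlap in the "
                        "same frame: contradictory codons"
                    )

    def _anchor(self, block: int, codon_on_strand: str, strand: str) -> None:
        bases = codon_on_strand if strand == "+" else reverse_complement(codon_on_strand)
        for off, base in enumerate(bases):
            pos = block + off
            if pos in self.anchors and self.seq[pos] != base:
                raise SyntheticDataError(
                    f"anchor collision at offset {pos}: planted codons disagree"
                )
            self.seq[pos] = base
            self.anchors.add(pos)

    def _covering_orfs(self, pos: int):
        return [(s, e, st) for s, e, st in self.layout if s <= pos < e]

    def _legal(self, changes: dict[int, str]) -> bool:
        """Would applying ``changes`` keep all planted frames stop-free?"""
        if any(p in self.anchors for p in changes):
            return False
        trial = self.seq
        affected_blocks: set[tuple[int, str, int, int]] = set()
        for pos in changes:
            for s, e, st in self._covering_orfs(pos):
                affected_blocks.add((_codon_block(pos, s, e, st), st, s, e))
        saved = {p: trial[p] for p in changes}
        for p, b in changes.items():
            trial[p] = b
        ok = True
        for block, st, s, e in affected_blocks:
            if _block_codon(trial, block, st) in _STOPS:
                ok = False
                break
        for p, b in saved.items():
            trial[p] = b
        return ok

    def _apply(self, changes: dict[int, str]) -> None:
        for p, b in changes.items():
            self.seq[p] = b

    def plant(self) -> None:
        for start, end, strand in self.layout:
            if strand == "+":
                self._anchor(start, "ATG", "+")
                self._anchor(end - 3, "TAA", "+")
            else:
                self._anchor(end - 3, "ATG", "-")
                self._anchor(start, "TAA", "-")
        # clear in-frame stops from every planted body
        for start, end, strand in self.layout:
            for block in range(start, end, 3):
                self._fix_block(block, start, end, strand)
        self._place_upstream_guards()

    def _fix_block(self, block: int, start: int, end: int, strand: str) -> None:
        if _block_codon(self.seq, block, strand) not in _STOPS:
            return
        if all(block + off in self.anchors for off in range(3)):
            return  # an anchored codon (planted stop) — legitimate
        for off in self.rng.permutation(3):
            pos = block + int(off)
            if pos in self.anchors:
                continue
            for base in self.rng.permutation(_BASES):
                if base == self.seq[pos]:
                    continue
                changes = {pos: str(base)}
                saved = self.seq[pos]
                self.seq[pos] = str(base)
                still_stop = _block_codon(self.seq, block, strand) in _STOPS
                self.seq[pos] = saved
                if not still_stop and self._legal(changes):
                    self._apply(changes)
                    return
        raise SyntheticDataError(
            f"cannot clear stop codon at block {block} of ORF [{start},{end}){strand}"
        )

    def _place_upstream_guards(self) -> None:
        """Put an in-frame stop just 5' of each planted start when free."""
        for start, end, strand in self.layout:
            if strand == "+":
                block = start - 3
                codon = "TAA"
            else:
                block = end
                codon = "TAA"
            if block < 0 or block + 3 > self.spec.length:
                continue
            positions = range(block, block + 3)
            if any(p in self.anchors for p in positions):
                continue
            if any(self._covering_orfs(p) for p in positions):
                continue  # inside another ORF; repair loop handles if needed
            self._anchor(block, codon, strand)

    # -- spurious-ORF repair ------------------------------------------------

    def repair(self, max_iter: int = 500) -> list:
        planted = {(s, e, st) for s, e, st in self.layout}
        threshold = max(
            1, min((e - s) // 3 - 1 for s, e, st in self.layout)
        )
        strands = tuple(sorted({"+"} | {st for _, _, st in self.layout}))
        for _ in range(max_iter):
            record = SequenceRecord(id=self.genome_id, residues="".join(self.seq))
            found = find_orfs(record, min_protein_len=threshold, strands=strands)
            found_set = {(o.start, o.end, o.strand) for o in found}
            extras = sorted(found_set - planted)
            if not extras:
                missing = planted - found_set
                if missing:
                    raise SyntheticDataError(
                        f"planted ORF(s) not recoverable: {sorted(missing)}"
                    )
                return found
            self._break_orf(*extras[0])
        raise SyntheticDataError(
            "could not suppress spurious ORFs within the iteration budget; "
            "the requested layout appears infeasible"
        )

    def _break_orf(self, start: int, end: int, strand: str) -> None:
        """Destroy a spurious ORF without touching planted frames/anchors."""
        # candidate blocks in 5'->3' order on the ORF's strand, excluding
        # its own stop block (rewriting a stop into another stop is a no-op)
        if strand == "+":
            blocks = list(range(start, end - 3, 3))
        else:
            blocks = list(reversed(range(start + 3, end, 3)))
        for block in blocks:
            for stop in _STOPS:
                target = stop if strand == "+" else reverse_complement(stop)
                changes = {
                    block + off: target[off]
                    for off in range(3)
                    if self.seq[block + off] != target[off]
                }
                if changes and self._legal(changes):
                    self._apply(changes)
                    return
        # fallback: mutate one base of its start codon
        atg = blocks[0] if strand == "+" else _codon_block(end - 1, start, end, "-")
        for off in range(3):
            pos = atg + off
            for base in _BASES:
                if base == self.seq[pos]:
                    continue
                changes = {pos: base}
                if self._legal(changes):
                    self._apply(changes)
                    return
        raise SyntheticDataError(
            f"cannot break spurious ORF [{start},{end}){strand} without "
            "disturbing planted ORFs"
        )


def generate_genome(
    spec: GenomeSpec, genome_id: str = "synthetic_genome"
) -> tuple[SequenceRecord, GenomeAnnotation]:
    """Generate a genome with the planted ORF layout, plus its ground truth.

    The returned annotation is computed from the final sequence, so its
    proteins, UTR lengths and overlaps are exactly what the annotation
    module recovers at ``min_protein_len`` equal to the shortest planted
    protein. Deterministic for a fixed spec (including its seed).
    Infeasible layouts (same-frame overlaps, colliding anchors) raise
    :class:`SyntheticDataError`.
    """
    if not spec.orf_layout:
        rng = np.random.default_rng(spec.seed)
        probs = [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
        residues = "".join(rng.choice(_BASES, size=spec.length, p=probs))
        record = SequenceRecord(id=genome_id, residues=residues)
        return record, GenomeAnnotation(
            genome_id=genome_id, genome_length=spec.length, orfs=[],
            utr5_length=0, utr3_length=0,
        )
    builder = _GenomeBuilder(spec, genome_id)
    builder.plant()
    orfs = builder.repair()
    record = SequenceRecord(id=genome_id, residues="".join(builder.seq))
    if any(o.strand == "+" for o in orfs):
        annotation = segment_genome(spec.length, orfs, genome_id=genome_id)
    else:
        # minus-only layout: UTR segmentation is plus-strand-relative
        annotation = GenomeAnnotation(
            genome_id=genome_id, genome_length=spec.length,
            orfs=sorted(orfs, key=lambda o: (o.start, o.end)),
            utr5_length=0, utr3_length=0,
            overlaps=detect_overlaps(sorted(orfs, key=lambda o: (o.start, o.end))),
        )
    return record, annotation


# ---------------------------------------------------------------------------
# sRNA library generation
# ---------------------------------------------------------------------------

@dataclass
class LibrarySpec:
    """Statistical shape of a synthetic small-RNA library."""

    n_reads: int = 50_000
    size_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SIZE_PROBS)
    )
    strand_prob_sense: float = 0.5
    five_prime_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FIVE_PRIME_PROBS)
    )
    bias_length: int = 21
    hotspot_spec: list[tuple[str, int, int, float]] = field(default_factory=list)
    host_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if not math.isclose(sum(self.size_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("size_probs must sum to 1")
        for length in self.size_probs:
            if not MIN_SRNA_LEN <= length <= MAX_SRNA_LEN:
                raise ValueError(f"read length {length} outside 18-30 nt window")
        if not math.isclose(sum(self.five_prime_probs.values()), 1.0, abs_tol=1e-9):
            raise ValueError("five_prime_probs must sum to 1")
        if set(self.five_prime_probs) - {"A", "C", "G", "U"}:
            raise ValueError("five_prime_probs keys must be RNA bases A/C/G/U")
        if not 0.0 <= self.strand_prob_sense <= 1.0:
            raise ValueError("strand_prob_sense must lie in [0, 1]")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction must lie in [0, 1]")
        for strand, start, end, mult in self.hotspot_spec:
            if strand not in (SENSE, ANTISENSE):
                raise ValueError(f"hotspot strand must be sense/antisense, got {strand!r}")
            if start >= end or mult <= 0:
                raise ValueError("hotspot intervals need start < end and rate > 0")


def default_library_spec(n_reads: int = 50_000, seed: int = 0, **kwargs) -> LibrarySpec:
    """The canonical study-condition library: 21-nt peak 0.60, strands
    50/50, 5' composition U 0.40 / A 0.35 / C 0.15 / G 0.10, no host reads."""
    return LibrarySpec(n_reads=n_reads, seed=seed, **kwargs)


def _position_weights(spec: LibrarySpec, genome_length: int) -> dict[str, np.ndarray]:
    weights = {
        SENSE: np.ones(genome_length, dtype=float),
        ANTISENSE: np.ones(genome_length, dtype=float),
    }
    for strand, start, end, mult in spec.hotspot_spec:
        weights[strand][start:end] *= mult
    return weights


def generate_library(
    genome: SequenceRecord, spec: LibrarySpec
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw a synthetic sRNA library from a genome, with its truth table.

    Viral reads are exact genome substrings (reverse-complemented for
    antisense draws); their 5'-start positions are uniform apart from
    hotspot multipliers, and at the bias length the 5'-terminal base is
    made to follow ``five_prime_probs`` by sampling the start position
    conditionally on its 5' base. Host background reads are i.i.d. random
    sequences re-drawn until they match neither genome strand. The truth
    table records each read's origin, strand, 5' position and length.
    """
    L = len(genome)
    max_used = max((l for l, p in spec.size_probs.items() if p > 0), default=0)
    if L <= max_used:
        raise SyntheticDataError("genome must be longer than the longest read")
    rng = np.random.default_rng(spec.seed)
    seq = genome.residues
    rc_seq = reverse_complement(seq)
    n_viral = int(round(spec.n_reads * (1.0 - spec.host_fraction)))
    n_host = spec.n_reads - n_viral

    lengths = np.array(sorted(spec.size_probs), dtype=int)
    probs = np.array([spec.size_probs[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    read_lengths = rng.choice(lengths, size=n_viral, p=probs)
    is_sense = rng.random(n_viral) < spec.strand_prob_sense
    weights = _position_weights(spec, L)

    # prefix N counts: windows containing N are never drawn
    n_flags = np.frombuffer(seq.encode(), dtype=np.uint8) == ord("N")
    n_prefix = np.concatenate([[0], np.cumsum(n_flags)])

    def window_clean(left: np.ndarray, length: int) -> np.ndarray:
        return (n_prefix[left + length] - n_prefix[left]) == 0

    def candidates(strand: str, length: int, base: str | None) -> tuple[np.ndarray, np.ndarray]:
        if strand == SENSE:
            fp = np.arange(0, L - length + 1)
            left = fp
        else:
            fp = np.arange(length - 1, L)
            left = fp - length + 1
        clean = window_clean(left, length)
        fp, left = fp[clean], left[clean]
        if base is not None:
            dna = _RNA_TO_DNA[base]
            g = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
            if strand == SENSE:
                keep = g[fp] == dna
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}[dna]
                keep = g[fp] == comp
            fp = fp[keep]
        w = weights[strand][fp]
        return fp, w

    five_prime = np.empty(n_viral, dtype="U1")
    bias_mask = read_lengths == spec.bias_length
    rna_bases = sorted(spec.five_prime_probs)
    base_probs = np.array([spec.five_prime_probs[b] for b in rna_bases])
    five_prime[bias_mask] = rng.choice(rna_bases, size=int(bias_mask.sum()), p=base_probs)
    five_prime[~bias_mask] = ""

    fp_positions = np.empty(n_viral, dtype=int)
    groups: dict[tuple[str, int, str], np.ndarray] = {}
    strand_names = np.where(is_sense, SENSE, ANTISENSE)
    for idx in range(n_viral):
        key = (strand_names[idx], int(read_lengths[idx]), five_prime[idx])
        groups.setdefault(key, []).append(idx)  # type: ignore[arg-type]
    for (strand, length, base), members in groups.items():
        members = np.asarray(members)
        fp, w = candidates(strand, length, base or None)
        if fp.size == 0:
            raise SyntheticDataError(
                f"no eligible 5' start with base {base or 'any'} on the "
                f"{strand} strand for {length}-nt reads; the requested 5' "
                "composition is unattainable — use a longer genome"
            )
        w = w / w.sum()
        fp_positions[members] = rng.choice(fp, size=members.size, p=w)

    reads: list[ReadRecord] = []
    truth_rows: list[dict] = []
    for i in range(n_viral):
        length = int(read_lengths[i])
        fp = int(fp_positions[i])
        if is_sense[i]:
            left = fp
            residues = seq[left : left + length]
        else:
            left = fp - length + 1
            residues = rc_seq[L - left - length : L - left]
        rid = f"v{i}"
        reads.append(ReadRecord(id=rid, residues=residues))
        truth_rows.append(
            {
                "read_id": rid,
                "origin": "viral",
                "strand": SENSE if is_sense[i] else ANTISENSE,
                "five_prime_pos": fp,
                "length": length,
            }
        )

    host_lengths = rng.choice(lengths, size=n_host, p=probs)
    for i in range(n_host):
        length = int(host_lengths[i])
        for _attempt in range(100):
            residues = "".join(rng.choice(_BASES, size=length))
            if residues not in seq and residues not in rc_seq:
                break
        else:
            raise SyntheticDataError(
                "could not draw a host read absent from the genome"
            )
        rid = f"h{i}"
        reads.append(ReadRecord(id=rid, residues=residues))
        truth_rows.append(
            {
                "read_id": rid,
                "origin": "host",
                "strand": "",
                "five_prime_pos": -1,
                "length": length,
            }
        )

    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([truth_rows[i] for i in order]).reset_index(drop=True)
    return reads, truth


# ---------------------------------------------------------------------------
# triage fixtures
# ---------------------------------------------------------------------------

@dataclass
class TriageFixture:
    """A candidate-contig table with planted truth labels."""

    contigs: list[SequenceRecord]
    viral_hits: list[TabularHit]
    all_hits: list[TabularHit]
    truth: pd.DataFrame


def generate_triage_fixture(
    n_candidates: int, n_viral: int, seed: int = 0
) -> TriageFixture:
    """Build a screened candidate set with planted viral/host labels.

    Every candidate passes the viral-homology screen (contig length >= 3000
    nt, viral-reference E-value <= 1e-20). Exactly ``n_viral`` contigs get a
    comprehensive-search best hit of category viral; the rest get a cellular
    best hit outscoring their viral hit — mimicking the typical outcome in
    which nearly all viral-screen candidates turn out to be host-derived.
    """
    if n_viral > n_candidates:
        raise ValueError("n_viral must be <= n_candidates")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_candidates)))
    ids = [f"contig_{i:0{width}d}" for i in range(1, n_candidates + 1)]
    viral_ids = set(rng.choice(ids, size=n_viral, replace=False)) if n_viral else set()

    contigs: list[SequenceRecord] = []
    for cid in ids:
        length = int(rng.integers(3000, 8001))
        residues = "".join(rng.choice(_BASES, size=length))
        contigs.append(SequenceRecord(id=cid, residues=residues))

    def _hit(cid: str, subject: str, evalue: float, bitscore: float, category: str) -> TabularHit:
        aln = int(rng.integers(100, 1000))
        return TabularHit(
            query_id=cid,
            subject_id=subject,
            percent_identity=float(rng.uniform(25, 70)),
            aln_length=aln,
            mismatches=int(rng.integers(0, aln // 2 + 1)),
            gap_opens=int(rng.integers(0, 5)),
            q_start=1,
            q_end=aln,
            s_start=1,
            s_end=aln,
            evalue=evalue,
            bitscore=round(float(bitscore), 1),
            subject_category=category,
        )

    viral_hits: list[TabularHit] = []
    all_hits: list[TabularHit] = []
    truth_rows: list[dict] = []
    for cid in ids:
        screen_evalue = 10.0 ** rng.uniform(-40, -21)
        viral_hits.append(
            _hit(cid, f"viral_ref_{int(rng.integers(1, 200)):03d}", screen_evalue,
                 rng.uniform(80, 200), "unknown")
        )
        if cid in viral_ids:
            all_hits.append(
                _hit(cid, f"virus_protein_{int(rng.integers(1, 100)):03d}",
                     10.0 ** rng.uniform(-120, -40), rng.uniform(400, 900), "viral")
            )
            label = "viral"
        else:
            cell_score = rng.uniform(500, 900)
            all_hits.append(
                _hit(cid, f"insect_protein_{int(rng.integers(1, 5000)):04d}",
                     10.0 ** rng.uniform(-150, -60), cell_score, "cellular")
            )
            # the incidental viral match that triggered the screen, outscored
            all_hits.append(
                _hit(cid, f"virus_protein_{int(rng.integers(1, 100)):03d}",
                     10.0 ** rng.uniform(-40, -21), rng.uniform(80, cell_score - 100),
                     "viral")
            )
            label = "host_derived"
        truth_rows.append({"contig_id": cid, "label": label})

    return TriageFixture(
        contigs=contigs,
        viral_hits=viral_hits,
        all_hits=all_hits,
        truth=pd.DataFrame(truth_rows),
    )
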