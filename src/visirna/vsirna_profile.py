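"""Virus-derived siRNA signature statistics.

An active siRNA-mediated antiviral response leaves a characteristic imprint
on the small RNAs that map to a viral genome: a sharp size peak at the
Dicer product length (21 nt here), reads drawn from both genomic strands in
comparable amounts (the dsRNA replication intermediate is the substrate),
an A/U bias at the 5'-terminal nucleotide, and uneven positional coverage
with pronounced hotspots. This module computes each of those statistics
from zero-mismatch mapping records.

Two weightings run through every tally: *unique* counts each mapping record
once (one per collapsed read per site), *total* weights it by the read's
collapse count. 5'-nucleotide composition is reported in the RNA alphabet
(U for T) to match the field's plotting convention; everything else stays
in DNA letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .srna_mapping import ANTISENSE, SENSE, MappingRecord

__all__ = [
    "VsiRnaProfile",
    "Hotspot",
    "size_strand_distribution",
    "five_prime_composition",
    "au_bias",
    "positional_profile",
    "detect_hotspots",
    "strand_fraction",
    "compute_profile",
]

RNA_BASES = ("A", "C", "G", "U")
_DNA_TO_RNA = {"A": "A", "C": "C", "G": "G", "T": "U"}


@dataclass
class Hotspot:
    """One called hotspot interval (0-based half-open genome offsets)."""

    strand: str
    start: int
    end: int
    peak_count: float


@dataclass
class VsiRnaProfile:
    """Bundle of all vsiRNA signature statistics for one genome."""

    size_strand: pd.DataFrame
    five_prime: dict[str, pd.Series]
    positional: pd.DataFrame
    strand_fraction_sense: float
    hotspots: list[Hotspot]
    analysis_length: int = 21


def size_strand_distribution(
    mappings: list[MappingRecord], min_len: int = 18, max_len: int = 30
) -> pd.DataFrame:
    """Counts per (read length, strand) in unique and total weighting.

    Returns a DataFrame indexed by length (min_len..max_len, missing
    lengths as 0) with columns sense_unique, antisense_unique, sense_total,
    antisense_total.
    """
    lengths = range(min_len, max_len + 1)
    cols = ["sense_unique", "antisense_unique", "sense_total", "antisense_total"]
    table = pd.DataFrame(0, index=pd.Index(lengths, name="length"), columns=cols)
    for m in mappings:
        n = len(m.read)
        if n not in table.index:
            continue
        key = "sense" if m.strand == SENSE else "antisense"
        table.loc[n, f"{key}_unique"] += 1
        table.loc[n, f"{key}_total"] += m.read.count
    return table


def five_prime_composition(
    mappings: list[MappingRecord], length: int = 21, weighting: str = "total"
) -> pd.Series:
    """Base fractions at the read 5' terminus for one read length.

    The 5' base is the first base of the read *as sequenced* (reported as
    U for T). With no records of the requested length, all fractions are
    NaN rather than zero.
    """
    if weighting not in ("unique", "total"):
        raise ValueError(f"unknown weighting {weighting!r}")
    counts = dict.fromkeys(RNA_BASES, 0.0)
    total = 0.0
    for m in mappings:
        if len(m.read) != length:
            continue
        w = 1.0 if weighting == "unique" else float(m.read.count)
        counts[_DNA_TO_RNA[m.read.residues[0]]] += w
        total += w
    if total == 0:
        return pd.Series({b: float("nan") for b in RNA_BASES}, name=weighting)
    return pd.Series({b: counts[b] / total for b in RNA_BASES}, name=weighting)


def au_bias(composition: pd.Series) -> float:
    """Combined A+U fraction of a 5'-terminal composition (0.5 = no bias)."""
    a, u = float(composition["A"]), float(composition["U"])
    if math.isnan(a) or math.isnan(u):
        return float("nan")
    return a + u


def positional_profile(
    mappings: list[MappingRecord], genome_length: int
) -> pd.DataFrame:
    """Total-weighted 5'-start counts along the genome, split by strand.

    Returns a DataFrame of ``genome_length`` rows with non-negative
    ``sense`` and ``antisense`` columns; report writers render antisense
    negatively for the mirror-plot convention. Out-of-range positions raise.
    """
    sense = np.zeros(genome_length, dtype=float)
    antisense = np.zeros(genome_length, dtype=float)
    for m in mappings:
        if not 0 <= m.five_prime_pos < genome_length:
            raise ValueError(
                f"five_prime_pos {m.five_prime_pos} outside genome of "
                f"length {genome_length}"
            )
        (sense if m.strand == SENSE else antisense)[m.five_prime_pos] += m.read.count
    return pd.DataFrame({"sense": sense, "antisense": antisense})


def detect_hotspots(
    positional: np.ndarray | pd.Series,
    strand: str = SENSE,
    window: int = 21,
    quantile: float = 0.99,
    merge_gap: int = 10,
) -> list[Hotspot]:
    """Call hotspot intervals on one strand's positional count vector.

    The vector is smoothed with a centered moving sum of width ``window``;
    offsets whose smoothed value strictly exceeds the ``quantile`` quantile
    of all smoothed values (and is positive) are called, and called offsets
    separated by <= ``merge_gap`` are merged into intervals. Each interval
    reports its peak raw count. A flat profile calls nothing (nothing
    strictly exceeds the quantile).
    """
    counts = np.asarray(positional, dtype=float)
    if counts.ndim != 1:
        raise ValueError("positional counts must be one-dimensional")
    if np.any(counts < 0):
        raise ValueError("positional counts must be non-negative")
    if not counts.size or not counts.any():
        return []
    kernel = np.ones(window, dtype=float)
    smoothed = np.convolve(counts, kernel, mode="same")
    threshold = np.quantile(smoothed, quantile)
    called = np.flatnonzero((smoothed > threshold) & (smoothed > 0))
    if called.size == 0:
        return []
    intervals: list[Hotspot] = []
    run_start = prev = called[0]
    for pos in called[1:]:
        if pos - prev <= merge_gap:
            prev = pos
            continue
        intervals.append(_make_hotspot(counts, strand, run_start, prev))
        run_start = prev = pos
    intervals.append(_make_hotspot(counts, strand, run_start, prev))
    return intervals


def _make_hotspot(counts: np.ndarray, strand: str, first: int, last: int) -> Hotspot:
    return Hotspot(
        strand=strand,
        start=int(first),
        end=int(last) + 1,
        peak_count=float(counts[first : last + 1].max()),
    )


def strand_fraction(mappings: list[MappingRecord]) -> float:
    """Total-weighted fraction of mapped reads on the sense strand."""
    total = sum(m.read.count for m in mappings)
    if total == 0:
        return float("nan")
    sense = sum(m.read.count for m in mappings if m.strand == SENSE)
    return sense / total


def compute_profile(
    mappings: list[MappingRecord],
    genome_length: int,
    analysis_length: int = 21,
    min_len: int = 18,
    max_len: int = 30,
    hotspot_window: int = 21,
    hotspot_quantile: float = 0.99,
    hotspot_merge_gap: int = 10,
) -> VsiRnaProfile:
    """Compute the full vsiRNA signature bundle for one genome."""
    positional = positional_profile(mappings, genome_length)
    hotspots = detect_hotspots(
        positional["sense"],
        strand=SENSE,
        window=hotspot_window,
        quantile=hotspot_quantile,
        merge_gap=hotspot_merge_gap,
    ) + detect_hotspots(
        positional["antisense"],
        strand=ANTISENSE,
        window=hotspot_window,
        quantile=hotspot_quantile,
        merge_gap=hotspot_merge_gap,
    )
    return VsiRnaProfile(
        size_strand=size_strand_distribution(mappings, min_len, max_len),
        five_prime={
            "unique": five_prime_composition(mappings, analysis_length, "unique"),
            "total": five_prime_composition(mappings, analysis_length, "total"),
        },
        positional=positional,
        strand_fraction_sense=strand_fraction(mappings),
        hotspots=hotspots,
        analysis_length=analysis_length,
    )
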