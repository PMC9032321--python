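"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from visirna.seqio import reverse_complement

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.42) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(_BASES), size=length, p=probs))


def brute_force_orfs(
    seq: str, min_protein_len: int, strands: tuple[str, ...] = ("+",)
) -> set[tuple[int, int, str]]:
    """Independent ORF enumeration: every ATG is extended to its stop, then
    ORFs sharing a (stop, frame, strand) keep only the earliest ATG."""
    found: dict[tuple[int, int, str], int] = {}
    n = len(seq)
    for strand in strands:
        s = seq if strand == "+" else reverse_complement(seq)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= n and s[j : j + 3] not in _STOPS:
                j += 3
            if j + 3 > n:
                continue  # ran off the end without a stop
            end = j + 3
            if (end - i) // 3 - 1 < min_protein_len:
                continue
            key = (end, i % 3, strand)
            if key not in found or i < found[key]:
                found[key] = i
    out: set[tuple[int, int, str]] = set()
    for (end, _frame, strand), start in found.items():
        if strand == "+":
            out.add((start, end, "+"))
        else:
            out.add((n - end, n - start, "-"))
    return out


def naive_scan_occurrences(genome: str, query: str) -> set[tuple[int, str]]:
    """All-positions substring scan on both strands via repeated str.find."""
    hits: set[tuple[int, str]] = set()
    for target, strand in ((query, "sense"), (reverse_complement(query), "antisense")):
        pos = genome.find(target)
        while pos != -1:
            hits.add((pos, strand))
            pos = genome.find(target, pos + 1)
    return hits
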