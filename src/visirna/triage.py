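"""Candidate-virus triage of assembled metatranscriptome contigs.

Two-stage screen mirroring standard virome-discovery practice:

1. *Screen*: keep contigs with at least one viral-reference hit at
   E-value <= ``evalue_max`` (default 1e-20) and contig length >=
   ``min_contig_length`` (default 3000 nt). Both thresholds are inclusive.
2. *Classify*: re-examine each screened contig against a comprehensive
   search (nucleotide + protein databases, each hit carrying a subject
   category). The best hit — ranked by bitscore, then smaller E-value, then
   lexicographic subject id — decides the label: ``viral``, ``host_derived``
   (best hit is cellular), or ``unresolved`` (no hits, or best hit of
   unknown category; unknown is deliberately *not* promoted to viral, since
   the whole point of the second pass is to remove false positives).

Most candidate contigs in an insect metatranscriptome turn out to be
host-derived — endogenous sequences scoring incidentally against viral
proteins — so the summary reports the host-derived percentage prominently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import SequenceRecord, TabularHit

__all__ = [
    "TriageConfig",
    "TriageVerdict",
    "screen_candidates",
    "classify_contig",
    "triage_summary",
]


@dataclass
class TriageConfig:
    """Thresholds of the first-pass viral-homology screen."""

    evalue_max: float = 1e-20
    min_contig_length: int = 3000

    def __post_init__(self) -> None:
        if not self.evalue_max > 0:
            raise ValueError("evalue_max must be positive")
        if self.min_contig_length < 1:
            raise ValueError("min_contig_length must be >= 1")


@dataclass
class TriageVerdict:
    """Final call for one candidate contig."""

    contig_id: str
    passed_screen: bool
    best_hit: TabularHit | None = None
    label: str = "unresolved"
    #: bitscore of best hit minus best hit of the opposite category
    #: (viral vs cellular); NaN when either side is absent.
    margin: float = float("nan")

    def __post_init__(self) -> None:
        if self.label not in ("viral", "host_derived", "unresolved"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.label in ("viral", "host_derived") and self.best_hit is None:
            raise ValueError(f"{self.contig_id}: label {self.label} requires a best hit")
        if not self.passed_screen and self.label != "unresolved":
            raise ValueError(f"{self.contig_id}: failed screen must be unresolved")


def screen_candidates(
    contigs: list[SequenceRecord],
    viral_hits: list[TabularHit],
    config: TriageConfig | None = None,
) -> list[str]:
    """Return ids of contigs passing the viral-homology screen.

    A contig passes when it has >= 1 viral-reference hit with
    ``evalue <= config.evalue_max`` and its length is
    ``>= config.min_contig_length``. Output preserves input contig order.
    Hits referencing contig ids absent from ``contigs`` raise ``ValueError``
    listing the orphans.
    """
    config = config or TriageConfig()
    known = {c.id for c in contigs}
    orphans = sorted({h.query_id for h in viral_hits} - known)
    if orphans:
        raise ValueError(
            f"hits reference unknown contig id(s): {', '.join(orphans)}"
        )
    passing = {
        h.query_id for h in viral_hits if h.evalue <= config.evalue_max
    }
    return [
        c.id
        for c in contigs
        if c.id in passing and len(c) >= config.min_contig_length
    ]


def _hit_rank(hit: TabularHit) -> tuple:
    # maximal bitscore wins; ties broken by smaller evalue, then subject id
    return (-hit.bitscore, hit.evalue, hit.subject_id)


def classify_contig(contig_id: str, all_hits: list[TabularHit]) -> TriageVerdict:
    """Label one screened contig from its comprehensive-search hits."""
    hits = [h for h in all_hits if h.query_id == contig_id]
    if not hits:
        return TriageVerdict(contig_id=contig_id, passed_screen=True, label="unresolved")
    best = min(hits, key=_hit_rank)
    label = {"viral": "viral", "cellular": "host_derived", "unknown": "unresolved"}[
        best.subject_category
    ]
    margin = float("nan")
    best_viral = min(
        (h for h in hits if h.subject_category == "viral"), key=_hit_rank, default=None
    )
    best_cell = min(
        (h for h in hits if h.subject_category == "cellular"), key=_hit_rank, default=None
    )
    if best_viral is not None and best_cell is not None:
        margin = best_viral.bitscore - best_cell.bitscore
    return TriageVerdict(
        contig_id=contig_id,
        passed_screen=True,
        best_hit=best,
        label=label,
        margin=margin,
    )


def triage_summary(verdicts: list[TriageVerdict]) -> dict:
    """Count verdict labels and compute the host-derived percentage.

    ``percent_host_derived`` is 100 * host / candidates rounded to one
    decimal, or NaN for an empty verdict list.
    """
    n = len(verdicts)
    host = sum(v.label == "host_derived" for v in verdicts)
    viral = sum(v.label == "viral" for v in verdicts)
    unresolved = sum(v.label == "unresolved" for v in verdicts)
    percent = round(100.0 * host / n, 1) if n else float("nan")
    return {
        "candidates": n,
        "host_derived": host,
        "viral": viral,
        "unresolved": unresolved,
        "percent_host_derived": percent,
    }
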