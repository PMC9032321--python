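"""Ground-truth generators: determinism, planted-structure recovery."""

from __future__ import annotations

import numpy as np
import pytest

from visirna.errors import SyntheticDataError
from visirna.genome_annotation import find_orfs, segment_genome
from visirna.seqio import reverse_complement
from visirna.srna_mapping import build_index, collapse, extract_by_length, map_exact
from visirna.synthetic_data import (
    GenomeSpec,
    LibrarySpec,
    default_library_spec,
    generate_genome,
    generate_library,
    generate_triage_fixture,
    iflavirus_like_genome_spec,
    nido_like_genome_spec,
)
from visirna.triage import classify_contig, screen_candidates


class TestGenerateGenome:
    def test_single_orf_preset_segments_exactly(self):
        record, truth = generate_genome(iflavirus_like_genome_spec(seed=11))
        orfs = find_orfs(record, min_protein_len=100)
        ann = segment_genome(len(record), orfs)
        assert (ann.utr5_length, ann.orfs[0].span, ann.utr3_length) == (181, 9297, 238)
        assert truth.utr5_length == 181 and truth.utr3_length == 238

    def test_four_orf_preset_has_single_overlap(self):
        record, truth = generate_genome(nido_like_genome_spec(seed=11))
        min_aa = min(len(o.protein) for o in truth.orfs)
        orfs = find_orfs(record, min_protein_len=min_aa)
        ann = segment_genome(len(record), orfs)
        assert len(ann.orfs) == 4
        assert (ann.utr5_length, ann.utr3_length) == (76, 1046)
        assert len(ann.overlaps) == 1
        i, j, ov = ann.overlaps[0]
        assert (i, j) == (2, 3) and ov == 22

    def test_deterministic_per_seed(self):
        a, _ = generate_genome(nido_like_genome_spec(seed=5))
        b, _ = generate_genome(nido_like_genome_spec(seed=5))
        c, _ = generate_genome(nido_like_genome_spec(seed=6))
        assert a.residues == b.residues
        assert a.residues != c.residues

    def test_same_frame_overlap_is_infeasible(self):
        spec = GenomeSpec(length=600, orf_layout=[(0, 300, "+"), (150, 450, "+")])
        with pytest.raises(SyntheticDataError, match="same frame"):
            generate_genome(spec)

    def test_minus_strand_orf_planted(self):
        spec = GenomeSpec(length=800, orf_layout=[(100, 400, "-")], seed=2)
        record, truth = generate_genome(spec)
        got = find_orfs(record, min_protein_len=99, strands=("-",))
        assert [(o.start, o.end, o.strand) for o in got] == [(100, 400, "-")]

    def test_truth_proteins_match_sequence(self):
        record, truth = generate_genome(nido_like_genome_spec(seed=3))
        for orf in truth.orfs:
            cds = record.residues[orf.start : orf.end]
            assert not any(
                cds[i : i + 3] in ("TAA", "TAG", "TGA")
                for i in range(0, len(cds) - 3, 3)
            )
            assert cds.startswith("ATG") and cds[-3:] in ("TAA", "TAG", "TGA")


@pytest.fixture(scope="module")
def genome():
    record, _ = generate_genome(iflavirus_like_genome_spec(seed=1))
    return record


class TestGenerateLibrary:
    def test_deterministic(self, genome):
        spec = default_library_spec(n_reads=500, seed=9)
        reads_a, truth_a = generate_library(genome, spec)
        reads_b, truth_b = generate_library(genome, spec)
        assert [r.residues for r in reads_a] == [r.residues for r in reads_b]
        assert truth_a.equals(truth_b)

    def test_pure_host_library_never_maps(self, genome):
        spec = default_library_spec(n_reads=300, seed=4, host_fraction=1.0)
        reads, truth = generate_library(genome, spec)
        assert (truth["origin"] == "host").all()
        index = build_index(genome)
        assert map_exact(collapse(extract_by_length(reads)), index) == []

    def test_pure_viral_library_maps_at_truth_positions(self, genome):
        spec = default_library_spec(n_reads=1000, seed=4)
        reads, truth = generate_library(genome, spec)
        index = build_index(genome)
        by_id = dict(zip(truth["read_id"], truth["five_prime_pos"]))
        strand_by_id = dict(zip(truth["read_id"], truth["strand"]))
        for read in reads:
            hits = index.lookup(read.residues)
            fp_expected = by_id[read.id]
            strand = strand_by_id[read.id]
            fives = [
                left if s == "sense" else left + len(read.residues) - 1
                for left, s in hits
                if s == strand
            ]
            assert fp_expected in fives

    def test_viral_reads_match_genome_exactly(self, genome):
        spec = default_library_spec(n_reads=400, seed=12)
        reads, truth = generate_library(genome, spec)
        truth = truth.set_index("read_id")
        for read in reads:
            row = truth.loc[read.id]
            fp, length = int(row["five_prime_pos"]), int(row["length"])
            assert len(read.residues) == length
            if row["strand"] == "sense":
                assert genome.residues[fp : fp + length] == read.residues
            else:
                left = fp - length + 1
                assert (
                    reverse_complement(genome.residues[left : left + length])
                    == read.residues
                )

    def test_empirical_distributions_converge_with_n(self, genome):
        spec_small = default_library_spec(n_reads=5000, seed=7)
        spec_large = default_library_spec(n_reads=50_000, seed=7)
        errors = {}
        for label, spec in (("small", spec_small), ("large", spec_large)):
            _, truth = generate_library(genome, spec)
            frac21 = (truth["length"] == 21).mean()
            sense = (truth["strand"] == "sense").mean()
            errors[label] = (
                abs(frac21 - spec.size_probs[21]),
                abs(sense - spec.strand_prob_sense),
            )
        shrunk = sum(l <= s for l, s in zip(errors["large"], errors["small"]))
        assert shrunk >= 1

    def test_genome_too_short_errors(self):
        record, _ = generate_genome(GenomeSpec(length=25, seed=0))
        with pytest.raises(SyntheticDataError, match="longer"):
            generate_library(record, default_library_spec(n_reads=10, seed=0))


class TestTriageFixture:
    def test_planted_counts_emerge(self):
        fixture = generate_triage_fixture(50, 3, seed=1)
        assert len(fixture.contigs) == 50
        assert (fixture.truth["label"] == "viral").sum() == 3
        passed = screen_candidates(fixture.contigs, fixture.viral_hits)
        assert len(passed) == 50  # every candidate passes the screen

    def test_truth_equals_triage_verdicts(self):
        """Planted labels are recovered by the triage module (the oracle is
        the planted truth) across many random fixtures."""
        rng = np.random.default_rng(55)
        for _ in range(50):
            n = int(rng.integers(2, 25))
            k = int(rng.integers(0, n + 1))
            fixture = generate_triage_fixture(n, k, seed=int(rng.integers(2**31)))
            passed = screen_candidates(fixture.contigs, fixture.viral_hits)
            labels = {
                cid: classify_contig(cid, fixture.all_hits).label for cid in passed
            }
            expected = dict(zip(fixture.truth["contig_id"], fixture.truth["label"]))
            assert labels == expected

    def test_deterministic(self):
        a = generate_triage_fixture(10, 2, seed=3)
        b = generate_triage_fixture(10, 2, seed=3)
        assert [c.residues for c in a.contigs] == [c.residues for c in b.contigs]
        assert a.truth.equals(b.truth)

    def test_n_viral_bounds(self):
        with pytest.raises(ValueError):
            generate_triage_fixture(5, 6, seed=0)
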