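"""Size/strand tallies, 5'-composition, A/U bias, positions, hotspots."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from visirna.srna_mapping import CollapsedRead, MappingRecord
from visirna.vsirna_profile import (
    au_bias,
    compute_profile,
    detect_hotspots,
    five_prime_composition,
    positional_profile,
    size_strand_distribution,
    strand_fraction,
)


def _rec(seq: str, count: int, strand: str, fp: int) -> MappingRecord:
    left = fp if strand == "sense" else fp - len(seq) + 1
    return MappingRecord(
        read=CollapsedRead(residues=seq, count=count),
        genome_id="g",
        left=left,
        strand=strand,
        five_prime_pos=fp,
    )


def _hand_set():
    # three distinct sense 21-mers (counts 5, 1, 1) + one antisense (count 7)
    return [
        _rec("T" + "A" * 20, 5, "sense", 0),
        _rec("A" * 21, 1, "sense", 30),
        _rec("G" + "C" * 20, 1, "sense", 60),
        _rec("C" * 21, 7, "antisense", 90),
    ]


class TestSizeStrand:
    def test_hand_counted(self):
        table = size_strand_distribution(_hand_set())
        assert table.loc[21, "sense_total"] == 7
        assert table.loc[21, "antisense_total"] == 7
        assert table.loc[21, "sense_unique"] == 3
        assert table.loc[21, "antisense_unique"] == 1
        assert table.drop(index=21).to_numpy().sum() == 0

    def test_empty_all_zero(self):
        table = size_strand_distribution([])
        assert table.to_numpy().sum() == 0 and len(table) == 13

    def test_unique_never_exceeds_total(self, rng):
        recs = [
            _rec("A" * int(n), int(c), "sense", int(p))
            for n, c, p in zip(
                rng.integers(18, 31, 50), rng.integers(1, 9, 50),
                rng.integers(100, 200, 50),
            )
        ]
        table = size_strand_distribution(recs)
        assert (table["sense_unique"] <= table["sense_total"]).all()
        assert (table["antisense_unique"] <= table["antisense_total"]).all()

    def test_permutation_invariant(self, rng):
        recs = _hand_set()
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        pd.testing.assert_frame_equal(
            size_strand_distribution(recs), size_strand_distribution(shuffled)
        )


class TestFivePrime:
    def test_unique_weighting(self):
        recs = [
            _rec("T" + "A" * 20, 1, "sense", 0),
            _rec("T" + "C" * 20, 1, "sense", 30),
            _rec("A" + "C" * 20, 1, "sense", 60),
            _rec("G" + "C" * 20, 1, "sense", 90),
        ]
        comp = five_prime_composition(recs, 21, "unique")
        assert comp.to_dict() == {"A": 0.25, "C": 0.0, "G": 0.25, "U": 0.5}

    def test_total_weighting_diverges(self):
        recs = [
            _rec("T" + "A" * 20, 1, "sense", 0),
            _rec("T" + "C" * 20, 1, "sense", 30),
            _rec("A" + "C" * 20, 1, "sense", 60),
            _rec("G" + "C" * 20, 97, "sense", 90),
        ]
        comp = five_prime_composition(recs, 21, "total")
        assert comp["G"] == pytest.approx(0.97)
        assert comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_absent_length_gives_na(self):
        comp = five_prime_composition(_hand_set(), 25)
        assert comp.isna().all()

    def test_restricted_to_requested_length(self):
        recs = _hand_set() + [_rec("G" * 22, 50, "sense", 200)]
        comp = five_prime_composition(recs, 21, "total")
        assert comp["G"] == pytest.approx(1 / 14)


class TestAuBias:
    def test_biased(self):
        comp = pd.Series({"A": 0.35, "C": 0.15, "G": 0.10, "U": 0.40})
        assert au_bias(comp) == pytest.approx(0.75)

    def test_uniform_baseline(self):
        comp = pd.Series({"A": 0.25, "C": 0.25, "G": 0.25, "U": 0.25})
        assert au_bias(comp) == pytest.approx(0.5)

    def test_na_propagates(self):
        assert math.isnan(au_bias(five_prime_composition([], 21)))


class TestPositional:
    def test_single_record(self):
        profile = positional_profile([_rec("A" * 21, 4, "sense", 10)], 100)
        assert profile.loc[10, "sense"] == 4
        assert profile.to_numpy().sum() == 4

    def test_sums_conserved_per_strand(self, rng):
        recs = [
            _rec("A" * 21, int(c), str(s), int(p))
            for c, s, p in zip(
                rng.integers(1, 9, 100),
                rng.choice(["sense", "antisense"], 100),
                rng.integers(20, 500, 100),
            )
        ]
        profile = positional_profile(recs, 600)
        assert profile["sense"].sum() == sum(
            r.read.count for r in recs if r.strand == "sense"
        )
        assert profile["antisense"].sum() == sum(
            r.read.count for r in recs if r.strand == "antisense"
        )

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="outside"):
            positional_profile([_rec("A" * 21, 1, "sense", 150)], 100)


class TestHotspots:
    def test_all_zero_empty(self):
        assert detect_hotspots(np.zeros(500)) == []

    def test_flat_profile_calls_nothing(self):
        assert detect_hotspots(np.full(1000, 3.0)) == []

    def test_single_spike_one_interval(self):
        counts = np.zeros(3000)
        counts[700] = 100
        (h,) = detect_hotspots(counts)
        assert h.start <= 700 < h.end and h.peak_count == 100

    def test_opposite_strand_hotspots_called_separately(self, rng):
        sense = rng.poisson(1.0, size=4000).astype(float)
        anti = rng.poisson(1.0, size=4000).astype(float)
        sense[1000:1040] += rng.poisson(10.0, size=40)
        anti[3000:3040] += rng.poisson(10.0, size=40)
        sense_calls = detect_hotspots(sense, strand="sense")
        anti_calls = detect_hotspots(anti, strand="antisense")
        assert any(h.start < 1040 and h.end > 1000 for h in sense_calls)
        assert any(h.start < 3040 and h.end > 3000 for h in anti_calls)
        assert not any(h.start < 3040 and h.end > 3000 for h in sense_calls)
        assert not any(h.start < 1040 and h.end > 1000 for h in anti_calls)


class TestStrandFraction:
    def test_balanced(self):
        recs = [_rec("A" * 21, 7, "sense", 5), _rec("C" * 21, 7, "antisense", 50)]
        assert strand_fraction(recs) == pytest.approx(0.5)

    def test_all_sense(self):
        assert strand_fraction([_rec("A" * 21, 3, "sense", 5)]) == 1.0

    def test_empty_na(self):
        assert math.isnan(strand_fraction([]))


class TestProfileBundle:
    def test_antisense_removal_zeroes_columns(self):
        recs = _hand_set()
        sense_only = [r for r in recs if r.strand == "sense"]
        profile = compute_profile(sense_only, genome_length=300)
        assert profile.strand_fraction_sense == 1.0
        assert profile.size_strand["antisense_total"].sum() == 0
        assert profile.positional["antisense"].sum() == 0
        assert not any(h.strand == "antisense" for h in profile.hotspots)

    def test_invariants_on_hand_set(self):
        profile = compute_profile(_hand_set(), genome_length=300)
        total_weight = sum(r.read.count for r in _hand_set())
        assert profile.size_strand[["sense_total", "antisense_total"]].to_numpy().sum() == total_weight
        assert profile.positional.to_numpy().sum() == total_weight
        for weighting in ("unique", "total"):
            assert profile.five_prime[weighting].sum() == pytest.approx(1.0, abs=1e-9)
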