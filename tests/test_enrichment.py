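"""Neighbor density, enrichment indexes, length statistics, matched
random samples, set overlaps and replicate correlation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iespipe import (
    IesAnnotation,
    enrichment_index,
    length_stats,
    matched_random_sample,
    neighbor_density,
    replicate_correlation,
    set_overlap,
)

IES = "TA" + "C" * 26  # 28 bp


def _anns(positions, replicon="chr", seq=IES):
    return [
        IesAnnotation(f"ies{k}", replicon, p, seq) for k, p in enumerate(positions)
    ]


class TestNeighborDensity:
    def test_hand_checked_example(self):
        dens = neighbor_density(_anns([100, 500, 1400, 5000]), window=1000)
        assert [dens[f"ies{k}"] for k in range(4)] == [1, 2, 1, 0]

    def test_single_ies_has_zero_density(self):
        assert neighbor_density(_anns([42])) == {"ies0": 0}

    def test_replicons_do_not_interact(self):
        anns = _anns([100], "chrA") + [IesAnnotation("other", "chrB", 100, IES)]
        dens = neighbor_density(anns)
        assert dens == {"ies0": 0, "other": 0}

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="single-copy"):
            neighbor_density(_anns([100, 100]))

    @given(
        st.lists(st.integers(0, 5000), min_size=1, max_size=60, unique=True),
        st.integers(50, 1500),
    )
    def test_matches_pairwise_bruteforce(self, positions, window):
        anns = _anns(positions)
        brute = {
            a.ies_id: sum(
                1
                for b in anns
                if b.ies_id != a.ies_id and abs(b.mac_position - a.mac_position) < window
            )
            for a in anns
        }
        assert neighbor_density(anns, window) == brute

    def test_symmetry(self):
        anns = _anns([0, 400, 950, 2000, 2600])
        dens = neighbor_density(anns)
        for a in anns:
            for b in anns:
                in_a = abs(a.mac_position - b.mac_position) < 1000 and a is not b
                in_b = abs(b.mac_position - a.mac_position) < 1000 and b is not a
                assert in_a == in_b


class TestEnrichmentIndex:
    def test_identity_gives_zero_everywhere(self):
        anns = _anns([0, 100, 2000, 5000, 9000])
        dens = neighbor_density(anns)
        table = enrichment_index([a.ies_id for a in anns], anns, dens)
        populated = table[table.n_universe > 0]
        assert (populated.ei.abs() < 1e-12).all()

    def test_hand_computed_two_class_universe(self):
        # 6 IESs in class 0 and 4 in class 2; retained = the class-2 four
        sparse = _anns([0, 3000, 6000, 9000, 12000, 15000])
        dense = [
            IesAnnotation(f"d{k}", "chr2", p, IES) for k, p in enumerate([0, 300, 600])
        ] + [IesAnnotation("d3", "chr2", 900, IES)]
        universe = sparse + dense
        dens = {a.ies_id: (2 if a.ies_id.startswith("d") else 0) for a in universe}
        table = enrichment_index([a.ies_id for a in dense], universe, dens)
        row = table[table.density_class == "2"].iloc[0]
        assert row.f_retained == pytest.approx(1.0)
        assert row.f_universe == pytest.approx(0.4)
        assert row.ei == pytest.approx(math.log2(1.0 / 0.4))
        # fractions over defined classes each sum to 1
        assert table.f_retained.sum() == pytest.approx(1.0, abs=1e-9)
        assert table.f_universe.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_classes_are_undefined_not_infinite(self):
        anns = _anns([0, 5000])
        dens = neighbor_density(anns)
        table = enrichment_index(["ies0"], anns, dens)
        empty = table[table.n_universe == 0]
        assert empty.ei.isna().all()

    def test_stray_retained_id_rejected(self):
        anns = _anns([0, 5000])
        with pytest.raises(ValueError):
            enrichment_index(["ghost"], anns, neighbor_density(anns))


class TestLengthStats:
    def test_peak_fraction(self):
        frac, _ = length_stats([26, 28, 30, 45])
        assert frac == pytest.approx(0.75)

    def test_cumulative_curve_saturates(self):
        _, ecdf = length_stats([26] * 5)
        assert ecdf(26) == 1.0
        assert ecdf(25) == 0.0

    def test_empty_set_flagged(self):
        frac, ecdf = length_stats([])
        assert math.isnan(frac) and math.isnan(ecdf(30))

    def test_short_restriction(self):
        frac, _ = length_stats([26, 28, 200, 300], max_length=150)
        assert frac == pytest.approx(1.0)


class TestMatchedSampling:
    def _universe(self):
        # 8 short IESs at 28 bp, 4 longer ones at 40 bp
        short = [
            IesAnnotation(f"s{k}", "chr", 1000 * k + 10, IES) for k in range(8)
        ]
        long_ = [
            IesAnnotation(f"l{k}", "chr", 1000 * k + 500, "TA" + "G" * 38)
            for k in range(4)
        ]
        return short + long_

    def test_exact_length_match(self):
        uni = self._universe()
        sample = matched_random_sample(uni, ["s0", "s1", "s2"], "length", rng_seed=1)
        assert len(sample) == 3
        by_id = {a.ies_id: a for a in uni}
        assert all(by_id[i].length == 28 for i in sample.ids)

    def test_shortfall_takes_all_available(self):
        uni = self._universe()[:3]  # only 3 length-28 IESs available
        ref = [f"x{k}" for k in range(5)]
        ref_anns = [IesAnnotation(x, "ref", 100 * k + 5, IES) for k, x in enumerate(ref)]
        sample = matched_random_sample(uni + ref_anns, ref, "length",
                                       rng_seed=0, exclude_reference=True)
        assert sample.requested == {28: 5}
        assert sample.obtained == {28: 3}
        assert len(sample) == 3

    def test_stratum_histogram_is_min_of_need_and_availability(self):
        uni = self._universe()
        ref = ["s0", "s1", "l0", "l1", "l2"]
        sample = matched_random_sample(uni, ref, "length", rng_seed=5)
        assert sample.obtained == {28: 2, 40: 3}

    def test_seed_reproducibility_and_variation(self):
        uni = self._universe()
        ref = ["s0", "s1", "s2", "l0"]
        a = matched_random_sample(uni, ref, "length", rng_seed=7)
        b = matched_random_sample(uni, ref, "length", rng_seed=7)
        assert a.ids == b.ids
        seen = {
            tuple(matched_random_sample(uni, ref, "length", rng_seed=s).ids)
            for s in range(12)
        }
        assert len(seen) > 1  # different seeds explore different draws
        for s in range(12):
            assert matched_random_sample(uni, ref, "length", rng_seed=s).obtained == a.obtained

    def test_density_matching_uses_classes(self):
        uni = self._universe()
        profile = {a.ies_id: (9 if a.ies_id.startswith("s") else 0) for a in uni}
        sample = matched_random_sample(uni, ["s0", "s1"], "density", profile, rng_seed=2)
        assert all(i.startswith("s") for i in sample.ids)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            matched_random_sample(self._universe(), [], "length")


class TestOverlapAndCorrelation:
    def test_identical_sets(self):
        out = set_overlap(["a", "b"], ["a", "b"])
        assert out["frac_of_a"] == out["frac_of_b"] == 1.0

    def test_disjoint_sets(self):
        out = set_overlap(["a"], ["b"])
        assert out["n_intersection"] == 0
        assert out["frac_of_a"] == 0.0

    def test_partial_overlap_enumerated(self):
        a = [str(i) for i in range(1, 11)]
        b = [str(i) for i in range(6, 21)]
        out = set_overlap(a, b)
        assert out["n_intersection"] == 5
        assert out["frac_of_a"] == pytest.approx(0.5)
        assert out["frac_of_b"] == pytest.approx(5 / 15)

    def test_identity_and_reversal(self):
        a = {"i1": 0.1, "i2": 0.4, "i3": 0.2, "i4": 0.9}
        rho, n = replicate_correlation(a, a)
        assert rho == pytest.approx(1.0)
        rev = {k: 1 - v for k, v in a.items()}
        rho, _ = replicate_correlation(a, rev)
        assert rho == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        # ranks a: [1,3,2,4], b: [2,3,1,4] -> sum d^2 = 2 -> rho = 0.8
        a = {"i1": 0.1, "i2": 0.4, "i3": 0.2, "i4": 0.9}
        b = {"i1": 0.2, "i2": 0.5, "i3": 0.1, "i4": 0.8}
        rho, n = replicate_correlation(a, b)
        assert n == 4
        assert rho == pytest.approx(0.8)

    def test_too_few_shared_scores_flagged(self):
        rho, n = replicate_correlation({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})
        assert math.isnan(rho) and n == 2

    def test_nan_scores_excluded(self):
        a = {"i1": 0.1, "i2": 0.4, "i3": 0.2, "i4": math.nan}
        b = {"i1": 0.1, "i2": 0.4, "i3": 0.2, "i4": 0.9}
        rho, n = replicate_correlation(a, b)
        assert n == 3
        assert rho == pytest.approx(1.0)
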