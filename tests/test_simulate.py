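"""Synthetic genome and read simulation: length mixture, packing, round
trips, retention models, coverage and the old/new-MAC mixture."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from iespipe import (
    GenerationError,
    SimulationConfig,
    SimulationTruth,
    assign_retention,
    excise_all,
    generate_genome_pair,
    neighbor_density,
    sample_ies_lengths,
    simulate_read_pairs,
)
from iespipe.validation import enumerate_expected_counts


class TestLengthMixture:
    def test_degenerate_first_peak(self):
        lengths = sample_ies_lengths(100, (1.0,), rng_seed=0)
        assert len(lengths) == 100
        assert all(26 <= ln <= 30 for ln in lengths)

    def test_empty_draw(self):
        assert sample_ies_lengths(0, (1.0,), rng_seed=0) == []

    def test_first_peak_fraction_within_exact_binomial_interval(self):
        n, w = 10_000, 0.7
        lengths = sample_ies_lengths(n, (w, 0.3), rng_seed=0)
        k = sum(26 <= ln <= 30 for ln in lengths)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, w)
        assert lo <= k <= hi

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": -1, "peak_weights": (1.0,)},
            {"n": 5, "peak_weights": (0.5, 0.4)},  # does not sum to 1
            {"n": 5, "peak_weights": (1.5, -0.5)},  # negative weight
        ],
    )
    def test_malformed_input_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sample_ies_lengths(**kwargs)

    @given(
        bin_idx=st.integers(0, 4),
        n=st.integers(1, 50),
        seed=st.integers(0, 2**20),
    )
    def test_lengths_always_inside_their_bin(self, bin_idx, n, seed):
        weights = tuple(1.0 if i == bin_idx else 0.0 for i in range(5))
        for ln in sample_ies_lengths(n, weights, rng_seed=seed):
            assert 26 + 10 * bin_idx <= ln <= 30 + 10 * bin_idx


class TestGenomePair:
    def test_excision_round_trip_over_many_seeds(self):
        for seed in range(100):
            cfg = SimulationConfig(replicon_length=6_000, n_ies=5, rng_seed=seed)
            mac, germ, anns = generate_genome_pair(cfg)
            assert excise_all(germ, anns) == mac
            total_ies = sum(a.length for a in anns)
            assert len(germ["scaffold_1"]) == len(mac["scaffold_1"]) + total_ies

    def test_annotation_invariants(self, small_instance):
        mac = small_instance["mac"]
        for ann in small_instance["annotations"]:
            assert ann.sequence.startswith("TA")
            assert mac[ann.replicon][ann.mac_position : ann.mac_position + 2] == "TA"
            assert ann.length >= 26

    def test_dense_regions_produce_high_neighbor_density(self):
        cfg = SimulationConfig(
            replicon_length=30_000,
            n_ies=24,
            cluster_fraction=0.5,
            dense_region_count=2,
            dense_region_span=2_000,
            rng_seed=4,
        )
        _, _, anns = generate_genome_pair(cfg)
        # brute-force pairwise oracle for the density
        pos = [(a.replicon, a.mac_position) for a in anns]
        brute = {
            a.ies_id: sum(
                1
                for rep, q in pos
                if rep == a.replicon and q != a.mac_position and abs(q - a.mac_position) < 1000
            )
            for a in anns
        }
        assert max(brute.values()) >= 3
        assert brute == neighbor_density(anns, 1000)

    def test_infeasible_packing_raises(self):
        with pytest.raises(GenerationError):
            generate_genome_pair(
                SimulationConfig(replicon_length=3_000, n_ies=50, rng_seed=0)
            )

    def test_seed_determinism(self):
        cfg = SimulationConfig(replicon_length=8_000, n_ies=6, rng_seed=9)
        assert generate_genome_pair(cfg) == generate_genome_pair(cfg)
        other = SimulationConfig(replicon_length=8_000, n_ies=6, rng_seed=10)
        assert generate_genome_pair(other) != generate_genome_pair(cfg)


class TestRetentionModels:
    def test_all_and_none(self, small_instance):
        anns, dens = small_instance["annotations"], small_instance["densities"]
        assert set(assign_retention(anns, dens, "all_retained").retention.values()) == {1.0}
        assert set(assign_retention(anns, dens, "none_retained").retention.values()) == {0.0}

    def test_unknown_model_rejected(self, small_instance):
        with pytest.raises(ValueError):
            assign_retention(
                small_instance["annotations"], small_instance["densities"], "bogus"
            )

    def test_missing_density_rejected(self, small_instance):
        with pytest.raises(ValueError):
            assign_retention(small_instance["annotations"], {}, "all_retained")

    def test_feature_logistic_matches_direct_evaluation(self, small_instance):
        anns, dens = small_instance["annotations"], small_instance["densities"]
        truth = assign_retention(
            anns, dens, "feature_logistic", b0=-4.0, b_len=3.0, b_dens=0.5
        )
        for a in anns:
            x = -4.0 + 3.0 * (a.length <= 30) + 0.5 * dens[a.ies_id]
            assert truth.retention[a.ies_id] == pytest.approx(1 / (1 + math.exp(-x)))
        short_dense = [
            truth.retention[a.ies_id]
            for a in anns
            if a.length <= 30 and dens[a.ies_id] >= 1
        ]
        long_isolated = [
            truth.retention[a.ies_id]
            for a in anns
            if a.length > 30 and dens[a.ies_id] == 0
        ]
        if short_dense and long_isolated:
            assert np.mean(short_dense) > np.mean(long_isolated)

    def test_planted_feature_property(self):
        """Under positive length/density effects, the true-retained set is
        shorter-skewed and denser than the universe."""
        cfg = SimulationConfig(
            n_replicons=1,
            replicon_length=80_000,
            n_ies=80,
            cluster_fraction=0.4,
            dense_region_count=4,
            dense_region_span=1_500,
            sparse_min_gap=700,
            dense_min_gap=60,
            dense_peak_weights=(0.45, 0.20, 0.12, 0.09, 0.06, 0.04, 0.02, 0.02),
            length_peak_weights=(0.30, 0.22, 0.16, 0.12, 0.08, 0.06, 0.04, 0.02),
            rng_seed=21,
        )
        _, _, anns = generate_genome_pair(cfg)
        dens = neighbor_density(anns)
        truth = assign_retention(anns, dens, "feature_logistic", b0=-4, b_len=2, b_dens=0.65)
        retained = [a for a in anns if truth.retention[a.ies_id] > 0.5]
        assert retained
        uni_peak = np.mean([a.length <= 30 for a in anns])
        ret_peak = np.mean([a.length <= 30 for a in retained])
        assert ret_peak > uni_peak
        assert np.mean([dens[a.ies_id] for a in retained]) > np.mean(
            [dens[a.ies_id] for a in anns]
        )


class TestReadSimulation:
    def test_mean_depth_matches_coverage(self):
        cfg = SimulationConfig(replicon_length=10_000, n_ies=5, rng_seed=1)
        mac, germ, anns = generate_genome_pair(cfg)
        truth = SimulationTruth({a.ies_id: 0.5 for a in anns}, rho=0.5)
        reads = simulate_read_pairs(mac, germ, anns, truth, coverage=50, rng_seed=2)
        depth = len(reads) * 2 * reads.read_length / 10_000
        assert depth == pytest.approx(50, rel=0.10)

    def test_rho_zero_is_pure_old_mac(self, small_instance):
        truth = SimulationTruth(
            {a.ies_id: 1.0 for a in small_instance["annotations"]}, rho=0.0
        )
        reads = simulate_read_pairs(
            small_instance["mac"], small_instance["germ"],
            small_instance["annotations"], truth, coverage=5, rng_seed=0,
        )
        assert {p.provenance for p in reads.pairs} == {"old_mac"}

    def test_full_retention_yields_no_excised_junction_reads(self, small_instance):
        from iespipe import count_and_score

        truth = SimulationTruth(
            {a.ies_id: 1.0 for a in small_instance["annotations"]}, rho=1.0
        )
        reads = simulate_read_pairs(
            small_instance["mac"], small_instance["germ"],
            small_instance["annotations"], truth, coverage=20, rng_seed=5,
        )
        assert all(p.provenance == "new_retained" or p.provenance == "new_excised"
                   for p in reads.pairs)
        records = count_and_score(reads, small_instance["library"])
        assert sum(r.counts.ies_minus for r in records) == 0

    def test_read_sim_determinism(self, small_instance):
        args = (
            small_instance["mac"], small_instance["germ"],
            small_instance["annotations"], small_instance["truth"],
        )
        a = simulate_read_pairs(*args, coverage=10, rng_seed=3)
        b = simulate_read_pairs(*args, coverage=10, rng_seed=3)
        assert a.pairs == b.pairs
        c = simulate_read_pairs(*args, coverage=10, rng_seed=4)
        assert c.pairs != a.pairs

    def test_counts_converge_to_enumeration_oracle(self):
        """Mixture property: simulated junction-vote totals match the
        exhaustive fragment-position enumeration at high coverage."""
        from iespipe import build_junction_library, count_and_score

        cfg = SimulationConfig(replicon_length=25_000, n_ies=30, sparse_min_gap=400, rng_seed=13)
        mac, germ, anns = generate_genome_pair(cfg)
        truth = SimulationTruth(
            {a.ies_id: 0.3 + 0.4 * (i % 2) for i, a in enumerate(anns)}, rho=0.5
        )
        coverage = 200
        reads = simulate_read_pairs(mac, germ, anns, truth, coverage=coverage, rng_seed=17)
        records = count_and_score(reads, build_junction_library(mac, germ, anns))
        n_frag = int(round(coverage * 25_000 / 200))
        expected = enumerate_expected_counts(mac, anns, truth, n_frag)
        tot_plus = sum(r.counts.ies_plus for r in records)
        tot_minus = sum(r.counts.ies_minus for r in records)
        exp_plus = sum(e.e_plus for e in expected.values())
        exp_minus = sum(e.e_minus for e in expected.values())
        assert tot_plus == pytest.approx(exp_plus, rel=0.10)
        assert tot_minus == pytest.approx(exp_minus, rel=0.10)
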