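"""Register arithmetic, window scores, tracks, radial profiles, Wilcoxon."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from phasecascade import (
    AlignedRead,
    GenomicInterval,
    LibraryStats,
    PhasingConfig,
    PhasingTrack,
    SimConfig,
    assign_register,
    dominant_registers,
    matched_coordinate_test,
    phasing_score,
    phasing_track,
    register_offset,
    register_radial,
    simulate_srna,
    window_phasing_score,
)
from phasecascade.phasing import RegisterProfile


class TestAssignRegister:
    @pytest.mark.parametrize(
        "position, anchor, expected",
        [(100, 100, 1), (121, 100, 1), (110, 100, 11), (99, 100, 21)],
    )
    def test_cyclic_numbering_resets_after_21(self, position, anchor, expected):
        assert assign_register(position, anchor) == expected

    @settings(deadline=None, max_examples=100)
    @given(
        position=st.integers(-10_000, 10_000),
        anchor=st.integers(-10_000, 10_000),
        k=st.integers(-50, 50),
    )
    def test_periodicity_under_full_cycle_shifts(self, position, anchor, k):
        assert assign_register(position + 21 * k, anchor) == assign_register(position, anchor)
        assert 1 <= assign_register(position, anchor) <= 21


class TestRegisterOffset:
    @pytest.mark.parametrize(
        "r_from, r_to, expected", [(2, 11, 9), (7, 7, 0), (20, 8, 9), (11, 2, 12)]
    )
    def test_modular_offsets(self, r_from, r_to, expected):
        assert register_offset(r_from, r_to) == expected

    def test_registers_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            register_offset(0, 5)


class TestPhasingScore:
    def test_matches_direct_evaluation_of_formula(self):
        # P=90, U=0, k=9: 7 * ln(1 + 10*90/(1+0)) = 7 * ln(901)
        assert phasing_score(90, 0, 9) == pytest.approx(7 * math.log(901))

    def test_fewer_than_three_occupied_cycles_scores_zero(self):
        assert phasing_score(1e6, 0, 2) == 0.0

    def test_no_phased_abundance_scores_zero(self):
        assert phasing_score(0, 50, 9) == 0.0

    def test_raw_numerator_variant_ignores_unphased_damping(self):
        assert phasing_score(90, 100, 9, "raw") == pytest.approx(7 * math.log(901))

    @settings(deadline=None, max_examples=60)
    @given(
        P=st.floats(0.1, 1e5),
        U=st.floats(0, 1e5),
        delta=st.floats(0.1, 1e4),
        k=st.integers(3, 18),
    )
    def test_monotone_increasing_in_phased_decreasing_in_unphased(self, P, U, delta, k):
        assert phasing_score(P + delta, U, k) > phasing_score(P, U, k)
        assert phasing_score(P, U + delta, k) <= phasing_score(P, U, k)

    def test_window_score_counts_registers_from_window_start(self):
        # nine phased sense positions, all counts in one register
        reads = [AlignedRead("chr1", 100 + 21 * j, 121 + 21 * j, "+", 10) for j in range(9)]
        cfg = PhasingConfig(min_covered_positions=1)
        score = window_phasing_score(reads, 100, cfg)
        assert score == pytest.approx(phasing_score(90, 0, 9))
        # out-of-register window start: everything becomes unphased
        assert window_phasing_score(reads, 101, cfg) == 0.0


class TestPhasingTrack:
    def test_noise_free_simulation_calls_only_in_register_coordinates(
        self, one_hit_locus, clean_cfg
    ):
        reads, truth = simulate_srna(one_hit_locus, clean_cfg)
        stats = LibraryStats.from_reads(reads)
        cfg = PhasingConfig()
        track = phasing_track(reads, one_hit_locus.span, cfg, stats)
        origin = one_hit_locus.to_genomic(one_hit_locus.phase_origin)
        assert track.calls, "saturated noise-free signal must produce calls"
        assert all((c - origin) % 21 == 0 for c in track.calls)
        # every in-register window covering the full phased block is called
        full_cover = [
            c for c in range(one_hit_locus.span.start, one_hit_locus.span.end - 189 + 1)
            if (c - origin) % 21 == 0 and c <= origin and c + 189 >= origin + 9 * 21
        ]
        assert full_cover and set(full_cover) <= set(track.calls)

    def test_empty_read_set_gives_empty_track(self):
        track = phasing_track([], GenomicInterval("chr1", 0, 400), PhasingConfig())
        assert track.scores == {} and track.calls == []

    def test_region_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="shorter than one"):
            phasing_track([], GenomicInterval("chr1", 0, 100), PhasingConfig())

    def test_pure_noise_rarely_calls(self, one_hit_locus):
        """Specificity: unphased libraries stay below threshold across seeds."""
        runs_with_calls = 0
        for seed in range(20):
            cfg = SimConfig(srna_depth=20_000, phased_fraction=0.0, seed=seed)
            reads, _ = simulate_srna(one_hit_locus, cfg)
            stats = LibraryStats.from_reads(reads)
            track = phasing_track(reads, one_hit_locus.span, PhasingConfig(), stats)
            runs_with_calls += bool(track.calls)
        assert runs_with_calls <= 1  # >= 95% of runs call nothing


class TestRegisterRadial:
    def test_noise_free_secondary_profile_is_single_spoke_at_register_2(
        self, one_hit_locus, clean_cfg
    ):
        reads, truth = simulate_srna(one_hit_locus, clean_cfg)
        stats = LibraryStats.from_reads(reads)
        profile = register_radial(reads, truth.anchor, PhasingConfig(), stats)
        nonzero = [r for r in range(1, 22) if profile[r] > 0]
        assert nonzero == [truth.secondary_register] == [2]

    def test_tertiary_cascade_adds_spoke_at_register_11(self, one_hit_locus):
        cfg = SimConfig(
            srna_depth=5000, phased_fraction=1.0, dcl2_fraction=0.0,
            tertiary_fraction=0.3, seed=8,
        )
        reads, truth = simulate_srna(one_hit_locus, cfg)
        stats = LibraryStats.from_reads(reads)
        profile = register_radial(reads, truth.anchor, PhasingConfig(), stats)
        nonzero = {r for r in range(1, 22) if profile[r] > 0}
        assert nonzero == {2, 11}
        assert register_offset(2, 11) == 9

    def test_uniform_reads_spread_evenly_over_spokes(self):
        rng = np.random.default_rng(12)
        counts = rng.multinomial(50_000, [1 / 2100] * 2100)
        reads = [
            AlignedRead("chr1", 1000 + i, 1021 + i, "+", int(c))
            for i, c in enumerate(counts) if c > 0
        ]
        stats = LibraryStats.from_reads(reads)
        profile = register_radial(reads, 1000, PhasingConfig(), stats)
        observed = profile.abundance / 1e6 * 50_000
        chi2, p = sps.chisquare(observed)
        assert p > 0.001

    def test_translation_invariance_of_profile(self, one_hit_locus, clean_cfg):
        reads, truth = simulate_srna(one_hit_locus, clean_cfg)
        stats = LibraryStats.from_reads(reads)
        base = register_radial(reads, truth.anchor, PhasingConfig(), stats)
        shift = 555
        moved = [
            AlignedRead(r.chrom, r.start + shift, r.end + shift, r.strand, r.count)
            for r in reads
        ]
        shifted = register_radial(moved, truth.anchor + shift, PhasingConfig(), stats)
        assert np.allclose(base.abundance, shifted.abundance)


class TestDominantRegisters:
    def test_single_spoke_ranks_first(self):
        abundance = np.zeros(21)
        abundance[4] = 10.0  # register 5
        profile = RegisterProfile(abundance, anchor=0, strand_policy="sense")
        assert dominant_registers(profile, 1) == [5]

    def test_all_zero_profile_orders_by_index(self):
        profile = RegisterProfile(np.zeros(21), anchor=0, strand_policy="sense")
        assert dominant_registers(profile, 3) == [1, 2, 3]

    def test_equal_spokes_tie_break_to_lower_register(self):
        abundance = np.zeros(21)
        abundance[4] = abundance[2] = 7.0  # registers 5 and 3
        profile = RegisterProfile(abundance, anchor=0, strand_policy="sense")
        assert dominant_registers(profile, 2) == [3, 5]


def _track(scores):
    return PhasingTrack(scores=scores, threshold=150.0, config=PhasingConfig())


class TestMatchedCoordinateTest:
    def test_identical_tracks_give_p_one(self):
        track = _track({c: float(c) for c in range(10)})
        stat, p = matched_coordinate_test(track, track, list(range(10)))
        assert p == 1.0

    def test_uniformly_greater_track_gives_minimal_one_sided_mass(self):
        n = 10
        a = _track({c: 100.0 + c for c in range(n)})
        b = _track({c: float(c) for c in range(n)})
        _, p = matched_coordinate_test(a, b, list(range(n)))
        # extreme ranks: two-sided exact p = 2 / 2^n
        assert p == pytest.approx(2 / 2**n)

    def test_too_few_pairs_rejected(self):
        track = _track({0: 1.0})
        with pytest.raises(ValueError, match=">= 5"):
            matched_coordinate_test(track, track, [0, 1, 2, 3])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_small_n_p_equals_sign_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        diffs = rng.normal(size=n)
        while len(set(np.abs(diffs))) < n or np.any(diffs == 0):
            diffs = rng.normal(size=n)
        a = _track({c: 50.0 + diffs[c] for c in range(n)})
        b = _track({c: 50.0 for c in range(n)})
        _, p = matched_coordinate_test(a, b, list(range(n)))
        ranks = sps.rankdata(np.abs(diffs))
        dist = np.array([
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in itertools.product([0, 1], repeat=n)
        ])
        w_obs = ranks[diffs > 0].sum()
        p_oracle = min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))
        assert p == pytest.approx(p_oracle)


class TestParameterRecovery:
    def test_dominant_register_matches_truth_in_most_seeded_runs(self, one_hit_locus):
        hits = 0
        n_runs = 50
        for seed in range(n_runs):
            cfg = SimConfig(srna_depth=5000, seed=seed)
            reads, truth = simulate_srna(one_hit_locus, cfg)
            stats = LibraryStats.from_reads(reads)
            profile = register_radial(reads, truth.anchor, PhasingConfig(), stats)
            hits += dominant_registers(profile, 1) == [truth.secondary_register]
        assert hits >= 0.95 * n_runs

    def test_secondary_to_tertiary_offset_always_nine_noise_free(self, one_hit_locus):
        for seed in range(10):
            cfg = SimConfig(
                srna_depth=3000, phased_fraction=1.0, dcl2_fraction=0.0,
                tertiary_fraction=0.3, seed=seed,
            )
            reads, truth = simulate_srna(one_hit_locus, cfg)
            stats = LibraryStats.from_reads(reads)
            profile = register_radial(reads, truth.anchor, PhasingConfig(), stats)
            top_two = dominant_registers(profile, 2)
            assert register_offset(top_two[0], top_two[1]) == 9
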