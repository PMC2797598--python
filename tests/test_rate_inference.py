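"""Segment fitting, slope-to-velocity conversion and changepoint search."""

import numpy as np
import pytest

import forkdose as fd
from forkdose.fixtures import HT_SLOPES, ht_velocity_profile

MIN_BOUNDS_RIGHT = [94.0 / 360.0 * fd.DEFAULT_GENOME_LENGTH_BP / 1e6,
                    153.0 / 360.0 * fd.DEFAULT_GENOME_LENGTH_BP / 1e6]


def _min_profile(genome_map, noise_sd=0.0, seed=None):
    """HT-strain Min-medium profile from the tabulated slope structure."""
    probes = np.arange(500, genome_map.genome_length_bp, 1000, dtype=np.int64)
    vel = ht_velocity_profile("Min")
    growth = fd.GrowthLaw(44.0)
    if noise_sd == 0.0:
        return fd.expected_async_profile(vel, growth, genome_map, probes)
    return fd.sample_async_profile(vel, growth, genome_map, probes,
                                   noise_sd=noise_sd, seed=seed)


class TestFitSegments:
    @pytest.mark.parametrize("continuity", ["independent", "continuous"])
    def test_noiseless_recovery_exact(self, genome_map, continuity):
        profile = _min_profile(genome_map)
        fits = fd.fit_segments(profile, genome_map,
                               {"right": MIN_BOUNDS_RIGHT, "left": []},
                               continuity=continuity)
        by_arm = {(f.replichore_id, round(f.start_mbp, 2)): f for f in fits}
        truth = {("right", 0.0): 0.646, ("right", 1.1): 0.462,
                 ("left", 0.0): 0.408}
        for (arm, start), a_true in truth.items():
            f = by_arm[(arm, start)]
            assert f.slope == pytest.approx(a_true, abs=1e-6)

    def test_noisy_recovery_within_se(self, genome_map):
        """Fitted slope within 3 fitted SE of truth across seeded runs."""
        ok = 0
        n_runs = 20
        for seed in range(n_runs):
            profile = _min_profile(genome_map, noise_sd=0.05, seed=seed)
            fits = fd.fit_segments(profile, genome_map,
                                   {"right": MIN_BOUNDS_RIGHT, "left": []})
            head_on = [f for f in fits
                       if f.replichore_id == "right" and f.start_mbp < 0.1][0]
            ok += abs(head_on.slope - 0.646) <= 3 * head_on.slope_se
        assert ok >= n_runs - 1

    def test_unbiasedness(self, genome_map):
        """Mean slope over seeds within 2 SE-of-mean of truth."""
        probes = (np.arange(2000) * 1000 + 500).astype(np.int64)
        vel, growth = fd.VelocityProfile.uniform(50.0), fd.GrowthLaw(40.0)
        slopes = []
        for seed in range(50):
            p = fd.sample_async_profile(vel, growth, genome_map, probes,
                                        noise_sd=0.05, seed=seed)
            slopes.append(fd.fit_segments(p, genome_map, [])[0].slope)
        slopes = np.asarray(slopes)
        sem = slopes.std(ddof=1) / np.sqrt(slopes.size)
        assert abs(slopes.mean() - 0.5) <= 2 * sem

    def test_flat_profile_zero_slope(self, genome_map, right_arm_probes):
        rng = np.random.default_rng(0)
        p = fd.DosageProfile(right_arm_probes,
                             rng.normal(0, 0.05, right_arm_probes.size))
        f = fd.fit_segments(p, genome_map, [])[0]
        assert abs(f.slope) <= 3 * f.slope_se

    def test_ols_matches_brute_force(self, genome_map):
        """Independent-mode slope equals the covariance/variance ratio."""
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(np.arange(1000, 2_000_000, 997), 40,
                                 replace=False)).astype(np.int64)
        y = rng.normal(0, 0.2, pos.size)
        p = fd.DosageProfile(pos, y)
        f = fd.fit_segments(p, genome_map, [])[0]
        x = pos / 1e6
        brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean())**2)
        assert -f.slope == pytest.approx(brute, rel=1e-10)

    def test_too_few_probes_raises(self, genome_map):
        p = fd.DosageProfile([1000, 2000, 3000], [0.0, -0.1, -0.2])
        with pytest.raises(fd.DataSufficiencyError):
            fd.fit_segments(p, genome_map, [])


class TestVelocityConversion:
    def test_inverse_of_generator(self):
        f = fd.SegmentFit("right", 0.0, 1.0, 0.5, 0.01, 0.0, 100)
        v = fd.velocity_from_slope(f, fd.GrowthLaw(40.0))
        assert v.velocity_kb_min == pytest.approx(50.0)

    def test_tabulated_left_arm_speed(self):
        # a = 0.408 /Mbp at T = 44 min -> ~55.7 kb/min
        f = fd.SegmentFit("left", 0.0, 2.0, 0.408, 0.002, 0.0, 2000)
        v = fd.velocity_from_slope(f, fd.GrowthLaw(44.0))
        assert v.velocity_kb_min == pytest.approx(55.7, abs=0.05)

    def test_se_propagation(self):
        f = fd.SegmentFit("right", 0.0, 1.0, 0.5, 0.05, 0.0, 100)
        v = fd.velocity_from_slope(f, fd.GrowthLaw(40.0))
        assert v.velocity_se_kb_min == pytest.approx(50.0 * 0.1)

    def test_non_declining_rejected(self):
        f = fd.SegmentFit("right", 0.0, 1.0, -0.1, 0.01, 0.0, 100)
        with pytest.raises(ValueError):
            fd.velocity_from_slope(f, fd.GrowthLaw(40.0))

    def test_round_trip_parameter_recovery(self, genome_map):
        """Generator velocities recovered within 5% from noisy profiles."""
        vel = ht_velocity_profile("Min")
        growth = fd.GrowthLaw(44.0)
        for seed in range(10):
            profile = _min_profile(genome_map, noise_sd=0.05, seed=100 + seed)
            fits = fd.fit_segments(profile, genome_map,
                                   {"right": MIN_BOUNDS_RIGHT, "left": []})
            for f in fits:
                if f.replichore_id == "right" and f.end_mbp > 1.8:
                    continue  # beyond the tabulated pksE boundary
                est = fd.velocity_from_slope(f, growth)
                mid = 0.5 * (f.start_mbp + f.end_mbp)
                true_v = float(vel.arm(f.replichore_id).velocity_at(mid))
                assert est.velocity_kb_min == pytest.approx(true_v, rel=0.05)


class TestSpeedComparison:
    def test_head_on_vs_codirectional(self):
        ht = fd.SegmentFit("right", 0.0, 1.1, 0.646, 0.004, 0.0, 1100)
        cd = fd.SegmentFit("right", 1.1, 1.8, 0.462, 0.007, 0.0, 700)
        assert fd.percent_speed_change(ht, cd) == pytest.approx(28.5, abs=0.05)

    def test_vs_left_replichore(self):
        ht = fd.SegmentFit("right", 0.0, 1.1, 0.646, 0.004, 0.0, 1100)
        left = fd.SegmentFit("left", 0.0, 2.0, 0.408, 0.002, 0.0, 2000)
        assert fd.percent_speed_change(ht, left) == pytest.approx(36.8, abs=0.05)

    def test_equal_slopes_zero(self):
        f = fd.SegmentFit("right", 0.0, 1.0, 0.5, 0.01, 0.0, 100)
        assert fd.percent_speed_change(f, f) == 0.0

    def test_invariance_to_intercept_and_T(self, genome_map, right_arm_probes):
        growthA, growthB = fd.GrowthLaw(40.0), fd.GrowthLaw(80.0)
        vel = fd.VelocityProfile(
            fd.SegmentedVelocity.uniform(50.0),
            fd.SegmentedVelocity((1.0,), (50.0, 30.0)),
        )
        out = []
        for growth in (growthA, growthB):
            p = fd.expected_async_profile(vel, growth, genome_map,
                                          right_arm_probes)
            fits = fd.fit_segments(p, genome_map, {"right": [1.0], "left": []})
            out.append(fd.percent_speed_change(fits[1], fits[0]))
        assert out[0] == pytest.approx(out[1], abs=1e-9)


class TestStallSegments:
    def test_tabulated_stall_flagged(self):
        slopes = [0.64, 0.62, 0.65, 1.51]
        fits = [fd.SegmentFit("right", i * 0.3, (i + 1) * 0.3, a, 0.01, 0.0, 100)
                for i, a in enumerate(slopes)]
        flagged = fd.stall_segments(fits, fold_threshold=2.0)
        assert [f.slope for f in flagged] == [1.51]

    def test_equal_slopes_none_flagged(self):
        fits = [fd.SegmentFit("right", i * 0.3, (i + 1) * 0.3, 0.5, 0.01, 0.0, 100)
                for i in range(4)]
        assert fd.stall_segments(fits) == []

    def test_fold_one_flags_above_median(self):
        fits = [fd.SegmentFit("right", i * 0.3, (i + 1) * 0.3, a, 0.01, 0.0, 100)
                for i, a in enumerate([0.4, 0.5, 0.6])]
        flagged = fd.stall_segments(fits, fold_threshold=1.0)
        assert [f.slope for f in flagged] == [0.6]

    def test_single_segment_nothing_to_compare(self):
        fits = [fd.SegmentFit("right", 0.0, 1.0, 0.5, 0.01, 0.0, 100)]
        assert fd.stall_segments(fits) == []


class TestChangepoints:
    def test_single_slope_no_breakpoints(self, genome_map, right_arm_probes):
        rng = np.random.default_rng(0)
        y = -0.5 * right_arm_probes / 1e6 + rng.normal(0, 0.05, 2000)
        p = fd.DosageProfile(right_arm_probes, y)
        assert fd.detect_changepoints(p, genome_map) == []

    def test_two_slope_breakpoint_located(self, genome_map, right_arm_probes):
        """Slope change 0.4 -> 0.65 at 1.0 Mbp, noise 0.05, 1 kb spacing.

        Localization is information-limited here (the exact broken-stick
        MLE has a knot-error sd of ~22 kb at these settings), so the check
        is: always found within +-50 kb, majority within +-20 kb, no bias.
        """
        x = right_arm_probes / 1e6
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.where(x < 1.0, -0.4 * x, -0.4 - 0.65 * (x - 1.0))
            y = y + rng.normal(0, 0.05, x.size)
            cps = fd.detect_changepoints(fd.DosageProfile(right_arm_probes, y),
                                         genome_map)
            assert len(cps) == 1
            errors.append(cps[0] - 1.0)
        errors = np.asarray(errors)
        assert np.all(np.abs(errors) <= 0.05)
        assert np.sum(np.abs(errors) <= 0.02) >= 5
        assert abs(errors.mean()) <= 0.02

    def test_steep_stall_segment_bracketed(self, genome_map, right_arm_probes):
        """A short slope-1.51 segment flanked by 0.65 is cut out at both
        ends within +-20 kb (the strong-slope regime localizes well)."""
        x = right_arm_probes / 1e6
        b1, b2 = 0.9366, 1.1005
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            y = np.where(
                x < b1, -0.65 * x,
                np.where(x < b2, -0.65 * b1 - 1.51 * (x - b1),
                         -0.65 * b1 - 1.51 * (b2 - b1) - 0.65 * (x - b2)),
            )
            y = y + rng.normal(0, 0.05, x.size)
            cps = fd.detect_changepoints(fd.DosageProfile(right_arm_probes, y),
                                         genome_map)
            hits += (len(cps) == 2 and abs(cps[0] - b1) <= 0.02
                     and abs(cps[1] - b2) <= 0.02)
        assert hits >= 9

    def test_bad_penalty_rejected(self, genome_map, random_profile):
        with pytest.raises(ValueError):
            fd.detect_changepoints(random_profile, genome_map, penalty=-1.0)
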