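"""Resultant statistics, uniformity tests, CIs and circular correlations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cellpol as cp
from cellpol.circstats import _rao_statistic_deg

from conftest import circ_diff_deg


class TestResultantSummary:
    def test_concentrated_sample(self):
        s = cp.AngleSample.from_degrees([40.0] * 12)
        summ = cp.resultant_summary(s)
        assert summ.R == pytest.approx(1.0)
        assert summ.mean_deg == pytest.approx(40.0)
        assert summ.S == pytest.approx(0.0)

    def test_four_quadrants_cancel(self):
        s = cp.AngleSample.from_degrees([0, 90, 180, 270])
        assert cp.resultant_summary(s).R == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_angles(self):
        s = cp.AngleSample.from_degrees([0, 90])
        summ = cp.resultant_summary(s)
        assert summ.R == pytest.approx(math.sqrt(2) / 2, rel=1e-12)
        assert summ.mean_deg == pytest.approx(45.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cp.AngleSample(np.array([]))

    def test_weighted_mean(self):
        s = cp.AngleSample.from_degrees([0.0, 90.0], weights=[3.0, 1.0])
        summ = cp.resultant_summary(s)
        assert summ.mean_deg == pytest.approx(math.degrees(math.atan2(0.25, 0.75)))


class TestSignedPolarityIndex:
    def test_aligned_is_one(self):
        s = cp.AngleSample.from_degrees([30.0] * 5)
        assert cp.signed_polarity_index(s, 30.0).V == pytest.approx(1.0)

    def test_antialigned_is_minus_one(self):
        s = cp.AngleSample.from_degrees([210.0] * 5)
        assert cp.signed_polarity_index(s, 30.0).V == pytest.approx(-1.0)

    def test_half_resultant_at_sixty_degrees(self):
        # two angles at mu +- gamma give R = cos(gamma); gamma=60 -> R=0.5
        mu, gamma, alpha_p = 100.0, 60.0, 40.0  # mean is alpha_p + 60
        s = cp.AngleSample.from_degrees([mu - gamma, mu + gamma])
        summ = cp.signed_polarity_index(s, alpha_p)
        assert summ.R == pytest.approx(0.5, rel=1e-12)
        assert summ.V == pytest.approx(0.25, rel=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(1, 40),
        alpha_p=st.floats(0, 360, allow_nan=False),
        shift=st.floats(0, 360, allow_nan=False),
    )
    def test_identities_and_rotation_invariance(self, seed, n, alpha_p, shift):
        """V = c*R exactly; |V| <= R <= 1; S = 1 - R; co-rotating sample and
        reference leaves R and V unchanged."""
        rng = np.random.default_rng(seed)
        angles = rng.uniform(0, 360, size=n)
        s = cp.AngleSample.from_degrees(angles)
        summ = cp.signed_polarity_index(s, alpha_p)
        assert summ.V == pytest.approx(summ.c * summ.R, abs=1e-12)
        assert abs(summ.V) <= summ.R + 1e-12
        assert summ.R <= 1.0 + 1e-12
        assert summ.S == pytest.approx(1.0 - summ.R, abs=1e-12)
        rotated = cp.signed_polarity_index(
            cp.AngleSample.from_degrees(angles + shift), alpha_p + shift
        )
        assert rotated.R == pytest.approx(summ.R, abs=1e-9)
        assert rotated.V == pytest.approx(summ.V, abs=1e-9)


class TestAxialMode:
    def test_doubling_round_trip(self):
        """Axial von Mises at mu=130, kappa=8: mean recovered within 1 deg."""
        s = cp.sample_von_mises(500, math.radians(130.0), 8.0, seed=3, mode="axial")
        summ = cp.resultant_summary(s)
        assert circ_diff_deg(summ.mean_deg, 130.0, period=180.0) < 1.0

    def test_axial_v_score_uses_doubled_reference(self):
        s = cp.AngleSample.from_degrees([30.0] * 9, mode="axial")
        assert cp.signed_polarity_index(s, 30.0).V == pytest.approx(1.0)
        # orthogonal axis: doubled angles are antipodal -> V = -1
        assert cp.signed_polarity_index(s, 120.0).V == pytest.approx(-1.0)

    def test_axial_normalisation(self):
        s = cp.AngleSample.from_degrees([190.0], mode="axial")
        assert s.angles[0] == pytest.approx(math.radians(10.0))


@pytest.mark.parametrize("kappa", [0.5, 2.0, 8.0])
def test_von_mises_resultant_matches_bessel_ratio(kappa):
    s = cp.sample_von_mises(2000, 0.0, kappa, seed=int(kappa * 10))
    R = cp.resultant_summary(s).R
    assert abs(R - cp.mean_resultant_length(kappa)) < 0.02


class TestMeanCI:
    def test_zero_width_for_equal_angles(self):
        s = cp.AngleSample.from_degrees([75.0] * 30)
        lo, hi = cp.mean_ci(s)
        assert lo == pytest.approx(75.0, abs=1e-6)
        assert hi == pytest.approx(75.0, abs=1e-6)

    def test_bootstrap_and_dispersion_agree(self):
        s = cp.sample_von_mises(1000, math.radians(30.0), 4.0, seed=5)
        lo_d, hi_d = cp.mean_ci(s)
        # force the bootstrap branch via a tiny dispersion-threshold override
        from cellpol import circstats

        lo_b, hi_b = None, None
        old = circstats.SMALL_SAMPLE_N
        try:
            circstats.SMALL_SAMPLE_N = 10**9
            lo_b, hi_b = cp.mean_ci(s, seed=7)
        finally:
            circstats.SMALL_SAMPLE_N = old
        assert circ_diff_deg(lo_d, lo_b) < 2.0
        assert circ_diff_deg(hi_d, hi_b) < 2.0

    def test_interval_contains_mean(self):
        s = cp.sample_von_mises(40, math.radians(300.0), 4.0, seed=9)
        summ = cp.resultant_summary(s)
        lo, hi = cp.mean_ci(s, seed=1)
        assert cp.ci_contains(summ.mean_deg, lo, hi)

    def test_uniform_sample_ci_undefined(self):
        s = cp.AngleSample.from_degrees([0, 90, 180, 270])
        lo, hi = cp.mean_ci(s)
        assert math.isnan(lo) and math.isnan(hi)

    def test_simulation_coverage(self):
        """95% CI covers the true von Mises mean in >= 93% of replicates."""
        mu, hits, reps = 30.0, 0, 1000
        for r in range(reps):
            s = cp.sample_von_mises(500, math.radians(mu), 8.0, seed=1000 + r)
            lo, hi = cp.mean_ci(s, seed=r)
            hits += cp.ci_contains(mu, lo, hi)
        assert hits / reps >= 0.93


class TestRayleigh:
    def test_identical_angles_strongly_nonuniform(self):
        res = cp.rayleigh_test(cp.AngleSample.from_degrees([123.0] * 10))
        assert res.statistic == pytest.approx(10.0)
        assert res.p_value < 1e-3

    def test_uniform_grid_not_rejected(self):
        res = cp.rayleigh_test(cp.AngleSample.from_degrees(np.arange(0, 360, 10.0)))
        assert res.p_value > 0.99

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        angles = rng.vonmises(1.0, 1.5, size=60)
        z_ref, p_ref = pingouin.circ_rayleigh(angles)
        res = cp.rayleigh_test(cp.AngleSample(angles))
        assert res.statistic == pytest.approx(z_ref, rel=1e-9)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)


class TestVTest:
    def test_zero_v_gives_half(self):
        s = cp.AngleSample.from_degrees([0.0, 180.0, 0.0, 180.0])
        assert cp.v_test(s, 0.0).p_value == pytest.approx(0.5)

    def test_negative_v_gives_large_p(self):
        s = cp.AngleSample.from_degrees([170.0, 190.0, 180.0, 175.0])
        assert cp.v_test(s, 0.0).p_value > 0.5

    def test_consistent_with_signed_index(self):
        s = cp.sample_von_mises(50, 0.3, 2.0, seed=2)
        res = cp.v_test(s, 10.0)
        V = cp.signed_polarity_index(s, 10.0).V
        assert res.statistic == pytest.approx(V * math.sqrt(2 * s.n), rel=1e-12)


class TestWatsonAndRao:
    def test_equispaced_rao_is_zero(self):
        s = cp.AngleSample.from_degrees(np.arange(0, 360, 36.0))
        res = cp.rao_spacing_test(s)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.99

    def test_identical_angles_rao(self):
        """n=10 identical angles: one spacing of 360, nine of 0 -> U = 324."""
        s = cp.AngleSample.from_degrees([45.0] * 10)
        assert _rao_statistic_deg(s.angles) == pytest.approx(324.0)
        assert cp.rao_spacing_test(s).p_value < 0.01

    def test_watson_detects_concentration(self):
        s = cp.sample_von_mises(100, 0.0, 4.0, seed=8)
        assert cp.watson_test(s).p_value < 0.01

    def test_watson_uniform_grid(self):
        s = cp.AngleSample.from_degrees(np.arange(0, 360, 10.0))
        assert cp.watson_test(s).p_value > 0.5

    def test_rao_seeded_reproducibility(self):
        s = cp.sample_von_mises(30, 1.0, 1.0, seed=0)
        p1 = cp.rao_spacing_test(s, seed=42).p_value
        p2 = cp.rao_spacing_test(s, seed=42).p_value
        assert p1 == p2


class TestCircLinearCorr:
    def test_cosine_identity(self):
        s = cp.AngleSample.from_degrees(np.arange(0, 360, 5.0))
        x = np.cos(s.angles)
        assert cp.circ_linear_corr(s, x) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        angles = rng.uniform(0, 360, size=80)
        x = rng.normal(size=80) + np.cos(np.deg2rad(angles))
        r1 = cp.circ_linear_corr(cp.AngleSample.from_degrees(angles), x)
        r2 = cp.circ_linear_corr(cp.AngleSample.from_degrees(angles + 73.0), x)
        assert r2 == pytest.approx(r1, abs=1e-9)

    def test_independent_null_small(self):
        """Under independence n*r^2 is asymptotically chi2(2), so r stays
        below the 95% null quantile sqrt(chi2_0.95(2)/n) in ~95% of reps."""
        n, reps = 200, 40
        crit = math.sqrt(5.991 / n)
        hits = 0
        for r in range(reps):
            rng = np.random.default_rng(500 + r)
            s = cp.AngleSample(rng.uniform(0, 2 * math.pi, n))
            x = rng.normal(size=n)
            hits += cp.circ_linear_corr(s, x) < crit
        assert hits / reps >= 0.875  # 95% minus binomial noise at 40 reps

    def test_constant_x_is_nan(self):
        s = cp.AngleSample.from_degrees([0, 40, 80, 120, 160])
        assert math.isnan(cp.circ_linear_corr(s, np.ones(5)))

    def test_pingouin_cross_check(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        angles = rng.uniform(0, 2 * math.pi, size=100)
        x = np.sin(angles) + rng.normal(0, 0.5, size=100)
        r_ref, _ = pingouin.circ_corrcl(angles, x)
        got = cp.circ_linear_corr(cp.AngleSample(angles), x)
        assert got == pytest.approx(r_ref, abs=1e-9)


class TestCircCircCorr:
    def test_self_correlation_is_one(self, rng):
        a = cp.AngleSample(rng.uniform(0, 2 * math.pi, 50))
        assert cp.circ_circ_corr(a, a) == pytest.approx(1.0)

    def test_corotation_and_reflection(self, rng):
        angles = rng.uniform(0, 2 * math.pi, 50)
        a = cp.AngleSample(angles)
        b_shift = cp.AngleSample(angles + math.pi)
        b_neg = cp.AngleSample(-angles)
        assert cp.circ_circ_corr(a, b_shift) == pytest.approx(1.0, abs=1e-9)
        assert cp.circ_circ_corr(a, b_neg) == pytest.approx(-1.0, abs=1e-9)

    def test_independent_samples_small_rho(self):
        vals = []
        for r in range(30):
            a = cp.sample_von_mises(150, 0.0, 1.0, seed=r)
            b = cp.sample_von_mises(150, 2.0, 1.0, seed=1000 + r)
            vals.append(abs(cp.circ_circ_corr(a, b)))
        assert np.median(vals) < 0.12


class TestRoseHistogram:
    def test_bin_centre_counts(self):
        centres = np.arange(7.5, 360, 15.0)
        rose = cp.rose_histogram(cp.AngleSample.from_degrees(centres), n_bins=24)
        assert (rose.counts == 1).all()

    def test_axial_duplication(self):
        s = cp.AngleSample.from_degrees([10.0, 10.0, 100.0], mode="axial")
        rose = cp.rose_histogram(s, n_bins=24)
        assert rose.counts.sum() == 3
        assert np.array_equal(rose.duplicated, np.roll(rose.counts, 12))

    def test_count_conservation(self, rng):
        s = cp.AngleSample.from_degrees(rng.uniform(0, 360, 77))
        rose = cp.rose_histogram(s, n_bins=12)
        assert rose.counts.sum() == 77

    def test_invalid_bins(self):
        with pytest.raises(ValueError):
            cp.rose_histogram(cp.AngleSample.from_degrees([0.0]), n_bins=7)
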