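import numpy as np
import pytest

from modewalk import (
    DEFAULT_MODE_PARAMS,
    alpha_distribution,
    displacement_pdf,
    fit_alpha,
    fixture,
    msd,
    phase_space,
    simulate_mode_segment,
    successive_angle_density,
    turning_angle_heatmap,
    zigzag_fraction,
)
from modewalk.errors import FitError, NoDataError, RangeError
from modewalk.trajectory_stats import MSDCurve

from conftest import make_trajectory, mode_segments


def msd_oracle(pos, kmax):
    """All-pairs brute force time-averaged MSD."""
    out = np.zeros(kmax + 1)
    for k in range(1, kmax + 1):
        acc = [np.sum((pos[i + k] - pos[i]) ** 2) for i in range(len(pos) - k)]
        out[k] = np.mean(acc)
    return out


class TestMSD:
    def test_ballistic_closed_form(self, ballistic):
        curve = msd(ballistic, 30)
        np.testing.assert_allclose(curve.msd, 4.0 * curve.lags ** 2, atol=1e-9)

    def test_hand_example(self):
        curve = msd(make_trajectory([[0, 0], [1, 0], [1, 1]]), 2)
        assert curve.msd[1] == pytest.approx(1.0)
        assert curve.msd[2] == pytest.approx(2.0)

    def test_stationary_all_zero(self):
        curve = msd(fixture("stationary", {"n_points": 40}), 20)
        np.testing.assert_array_equal(curve.msd, 0.0)

    def test_matches_all_pairs_oracle(self):
        tr = fixture("brownian", {"n_points": 80}, seed=12)
        curve = msd(tr, 40)
        np.testing.assert_allclose(curve.msd, msd_oracle(tr.positions, 40),
                                   atol=1e-12)
        np.testing.assert_array_equal(curve.n_pairs[1:],
                                      80 - np.arange(1, 41))

    def test_lag_beyond_duration_rejected(self, ballistic):
        with pytest.raises(RangeError):
            msd(ballistic, 61)
        # lag == duration is admissible: one displacement pair remains
        assert msd(ballistic, 60).n_pairs[-1] == 1


class TestFitAlpha:
    def test_exact_power_law_recovered(self):
        lags = np.arange(31.0)
        curve = MSDCurve(lags=lags, msd=4.0 * lags ** 1.5, n_pairs=np.ones(31, int))
        assert fit_alpha(curve, (1, 30)) == pytest.approx(1.5, abs=1e-9)

    def test_ballistic_exponent_two(self, ballistic):
        assert fit_alpha(msd(ballistic, 30), (1, 30)) == pytest.approx(2.0, abs=1e-9)

    def test_brownian_ensemble_exponent_one(self):
        """Ensemble mean of 200 Brownian time-averaged MSDs has slope ~1."""
        curves = [msd(fixture("brownian", {"n_points": 301}, seed=s), 30).msd
                  for s in range(200)]
        mean_curve = np.mean(curves, axis=0)
        alpha = fit_alpha(MSDCurve(np.arange(31.0), mean_curve,
                                   np.ones(31, int)), (2, 30))
        assert alpha == pytest.approx(1.0, abs=0.1)

    def test_zero_msd_in_range_rejected(self):
        curve = MSDCurve(np.arange(31.0), np.zeros(31), np.ones(31, int))
        with pytest.raises(FitError):
            fit_alpha(curve, (10, 30))


class TestAlphaDistribution:
    def test_ballistic_pool_is_point_mass_at_two(self):
        pool = [fixture("ballistic", {"speed": v, "n_points": 61})
                for v in (1.0, 2.0, 3.0)]
        dist = alpha_distribution(pool, (1, 30))
        np.testing.assert_allclose(dist.alphas, 2.0, atol=1e-9)

    def test_fp_pool_narrower_than_sd_pool(self):
        sd = alpha_distribution(mode_segments("SD", 60, seed_base=1), (10, 30))
        fp = alpha_distribution(mode_segments("FP", 60, seed_base=2), (10, 30))
        iqr = lambda d: d.quantiles["q75"] - d.quantiles["q25"]
        assert iqr(fp) < iqr(sd)

    def test_singleton_pool(self, ballistic):
        dist = alpha_distribution([ballistic], (1, 30))
        assert dist.alphas.shape == (1,)
        assert dist.quantiles["q50"] == pytest.approx(2.0, abs=1e-9)


class TestDisplacementPDF:
    def test_density_integrates_to_one(self):
        pool = [fixture("brownian", {"n_points": 200}, seed=s) for s in range(5)]
        pdf = displacement_pdf(pool, 3)
        widths = np.diff(pdf.bin_edges)
        assert np.sum(pdf.density * widths) == pytest.approx(1.0, abs=1e-6)

    def test_brownian_pool_is_gaussian(self):
        from scipy import stats
        pool = [fixture("brownian", {"n_points": 500}, seed=s) for s in range(40)]
        xs = np.concatenate([tr.positions[1:, 0] - tr.positions[:-1, 0]
                             for tr in pool])
        assert abs(stats.kurtosis(xs)) < 0.1

    def test_ballistic_is_a_point_mass(self, ballistic):
        pdf = displacement_pdf([ballistic], 2)
        widths = np.diff(pdf.bin_edges)
        mass = pdf.density * widths
        assert mass.max() == pytest.approx(1.0, abs=1e-9)

    def test_empty_pool_rejected(self):
        with pytest.raises(NoDataError):
            displacement_pdf([], 1)


class TestTurningAngleHeatmap:
    def test_persistent_pool_peaks_at_zero(self):
        pool = mode_segments("FP", 40, seed_base=3)
        hm = turning_angle_heatmap(pool, [1, 3, 5])
        centers = (hm.bin_edges[:-1] + hm.bin_edges[1:]) / 2
        for j in range(hm.matrix.shape[1]):
            assert abs(centers[hm.matrix[:, j].argmax()]) < 0.2

    def test_anti_persistent_pool_peaks_at_pi_for_long_lags(self):
        pool = mode_segments("SD", 40, seed_base=4)
        hm = turning_angle_heatmap(pool, [5, 10])
        centers = (hm.bin_edges[:-1] + hm.bin_edges[1:]) / 2
        for j in range(hm.matrix.shape[1]):
            assert abs(centers[hm.matrix[:, j].argmax()]) > np.pi - 0.5

    def test_columns_sum_to_one(self):
        pool = mode_segments("SP", 10, seed_base=5)
        hm = turning_angle_heatmap(pool, [1, 2, 3])
        np.testing.assert_allclose(hm.matrix.sum(axis=0), 1.0, atol=1e-12)


class TestPhaseSpace:
    def test_constant_speed_zero_radial_rate(self, ballistic):
        series = phase_space(ballistic, 1)
        np.testing.assert_allclose(series.radial_rates, 0.0, atol=1e-9)

    def test_circle_has_zero_delta_theta(self, circle60):
        series = phase_space(circle60, 1)
        np.testing.assert_allclose(series.delta_thetas, 0.0, atol=1e-9)

    def test_zigzag_delta_theta_alternates_pm_pi(self, zigzag60):
        series = phase_space(zigzag60, 1)
        np.testing.assert_allclose(np.abs(series.delta_thetas), np.pi, atol=1e-9)
        assert np.all(series.delta_thetas[:-1] * series.delta_thetas[1:] < 0)

    def test_delta_thetas_one_shorter_than_thetas(self):
        tr = fixture("brownian", {"n_points": 100}, seed=13)
        series = phase_space(tr, 3)
        assert series.delta_thetas.size == series.thetas.size - 1


class TestZigzagFraction:
    def test_circle_is_zero(self, circle60):
        assert zigzag_fraction(circle60) == 0.0

    def test_sp_pool_above_one(self):
        assert zigzag_fraction(mode_segments("SP", 50, seed_base=6)) > 1.0

    def test_sd_pool_below_one(self):
        assert zigzag_fraction(mode_segments("SD", 50, seed_base=7)) < 1.0

    def test_reflection_invariant(self):
        tr = fixture("brownian", {"n_points": 200}, seed=14)
        mirrored = make_trajectory(tr.positions * [1, -1])
        assert zigzag_fraction(tr) == zigzag_fraction(mirrored)

    def test_straight_line_has_no_valid_pairs(self, ballistic):
        with pytest.raises(NoDataError):
            zigzag_fraction(ballistic)


class TestSuccessiveAngleDensity:
    def test_straight_line_pairs_all_zero(self, ballistic):
        out = successive_angle_density(ballistic, 1)
        np.testing.assert_allclose(out.pairs, 0.0, atol=1e-12)
        assert sum(out.quadrant_counts.values()) == 0

    def test_zigzag_occupies_opposite_sign_quadrants(self, zigzag60):
        out = successive_angle_density(zigzag60, 1)
        assert out.quadrant_counts["Q1"] == out.quadrant_counts["Q3"] == 0
        assert out.quadrant_counts["Q2"] > 0 and out.quadrant_counts["Q4"] > 0

    def test_pair_count_is_angle_count_minus_one(self):
        tr = fixture("brownian", {"n_points": 90}, seed=15)
        from modewalk.features import turning_angles
        out = successive_angle_density(tr, 1)
        assert out.pairs.shape[0] == turning_angles(tr).size - 1
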