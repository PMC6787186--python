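"""Trajectory estimators: conformational, persistence-length, transport,
Manning/occupancy/proximity."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from nanostripe import (
    ChainParams,
    ChainState,
    SurfacePattern,
    com_series,
    drift_velocity,
    effective_charge,
    end_to_end,
    fit_diffusion_1d,
    fit_mobility,
    fit_persistence_length,
    init_chain,
    manning_condensed_fraction,
    mean_spacing,
    msd,
    proximity_count,
    screening_fraction,
    tangent_correlation,
)
from nanostripe.analysis import EstimationError, domain_occupancy


class TestEndToEnd:
    def test_two_beads(self):
        assert end_to_end(ChainState([[0, 0], [0.625, 0]])) == pytest.approx(
            0.625)

    def test_ring_chord(self, default_params):
        st_ = init_chain(default_params, "circular")
        R = 20 * 0.625 / (2 * math.pi)
        expected = 2 * R * math.sin(19 * math.pi / 20)
        assert end_to_end(st_) == pytest.approx(expected, rel=1e-12)

    def test_straight_chain(self, default_params):
        assert end_to_end(init_chain(default_params, "linear")) == (
            pytest.approx(11.875))

    def test_per_frame_vector(self, short_free_traj):
        ee = end_to_end(short_free_traj)
        assert ee.shape == (short_free_traj.n_frames,)
        assert np.all(ee > 0)


class TestTangentCorrelation:
    def test_straight_chain_all_ones(self, default_params):
        st_ = init_chain(default_params, "linear")
        c = tangent_correlation(st_, max_sep=6)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_right_angle_zigzag(self):
        # tangents alternate +x, +y: neighbours orthogonal, N=2 parallel
        pos = [[0, 0], [1, 0], [1, 1], [2, 1], [2, 2], [3, 2]]
        c = tangent_correlation(ChainState(np.asarray(pos, float)), max_sep=2)
        assert c[1] == pytest.approx(0.0, abs=1e-12)
        assert c[2] == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_bond_excluded_with_warning(self):
        pos = np.zeros((1, 5, 2))
        pos[0, :, 0] = [0.0, 1.0, 2.0, 2.0, 3.0]  # one zero-length bond
        with pytest.warns(RuntimeWarning, match="zero-length"):
            c = tangent_correlation(pos, max_sep=1)
        # the only pair not touching the degenerate bond is parallel
        assert c[1] == pytest.approx(1.0)
        assert np.isfinite(c).all()

    def test_matches_bessel_ratio_oracle(self):
        """Chains with joint angles drawn from p ~ exp(kappa cos t) must
        give C(1) = I1(kappa)/I0(kappa); the oracle value comes from
        numerical quadrature, independent of any Bessel routine."""
        kappa = 1.5
        rng = np.random.default_rng(13)
        n_chains, n_beads = 4000, 20
        # rejection sampling from exp(kappa*(cos t - 1)) on (-pi, pi]
        angles = np.empty((n_chains, n_beads - 2))
        filled = 0
        while filled < angles.size:
            prop = rng.uniform(-math.pi, math.pi, size=2 * angles.size)
            acc = rng.random(prop.size) < np.exp(kappa * (np.cos(prop) - 1.0))
            take = prop[acc][: angles.size - filled]
            angles.flat[filled:filled + take.size] = take
            filled += take.size
        headings = np.concatenate(
            [np.zeros((n_chains, 1)), np.cumsum(angles, axis=1)], axis=1)
        steps = 0.625 * np.stack([np.cos(headings), np.sin(headings)], axis=2)
        pos = np.concatenate(
            [np.zeros((n_chains, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
        c = tangent_correlation(pos, max_sep=2)

        num = integrate.quad(
            lambda t: math.cos(t) * math.exp(kappa * math.cos(t)),
            -math.pi, math.pi)[0]
        den = integrate.quad(
            lambda t: math.exp(kappa * math.cos(t)), -math.pi, math.pi)[0]
        oracle = num / den
        n_samples = n_chains * (n_beads - 2)
        se = math.sqrt((1 - oracle**2) / n_samples)
        assert abs(c[1] - oracle) < 3 * se
        # independent joints: C(2) = C(1)^2
        assert c[2] == pytest.approx(oracle**2, abs=6 * se)

    def test_bounded(self, short_free_traj):
        c = tangent_correlation(short_free_traj, max_sep=8)
        assert np.all(c <= 1.0 + 1e-12) and np.all(c >= -1.0 - 1e-12)
        assert c[1] > 0  # stiff default chain


class TestPersistenceFit:
    @given(lp=st.floats(0.2, 30.0), a=st.floats(0.05, 2.0))
    @settings(max_examples=60, deadline=None)
    def test_exact_exponential_identity(self, lp, a):
        n = np.arange(9)
        corr = np.exp(-n * a / lp)
        fit = fit_persistence_length(corr, a, fit_range=(1, 6))
        assert fit.lp == pytest.approx(lp, rel=1e-9)

    def test_unit_decay(self):
        corr = np.exp(-np.arange(8).astype(float))
        assert fit_persistence_length(corr, 1.0).lp == pytest.approx(1.0)

    def test_default_example(self):
        corr = np.exp(-np.arange(8) * 0.625 / 1.39)
        fit = fit_persistence_length(corr, 0.625, fit_range=(1, 6))
        assert fit.lp == pytest.approx(1.39, rel=1e-9)
        assert fit.fit_range == (1, 6)

    def test_weighted_equals_unweighted_for_uniform_errors(self):
        corr = np.exp(-np.arange(8) * 0.5)
        se = np.full(8, 1e-3) * corr  # uniform errors in ln C
        lp_w = fit_persistence_length(corr, 1.0, stderr=se).lp
        lp_u = fit_persistence_length(corr, 1.0).lp
        assert lp_w == pytest.approx(lp_u, rel=1e-9)

    def test_nonpositive_truncates_with_warning(self):
        corr = np.array([1.0, 0.6, 0.35, -0.01, 0.1, 0.05, 0.02])
        with pytest.warns(RuntimeWarning, match="truncated"):
            fit = fit_persistence_length(corr, 1.0, fit_range=(1, 6))
        assert fit.fit_range == (1, 2)

    def test_too_few_points_is_error(self):
        corr = np.array([1.0, 0.5, -0.1, -0.2, -0.1, 0.0, 0.0])
        with pytest.warns(RuntimeWarning):
            with pytest.raises(EstimationError):
                fit_persistence_length(corr, 1.0, fit_range=(1, 6))

    def test_growing_correlations_is_error(self):
        corr = np.array([1.0, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95])
        with pytest.raises(EstimationError, match="non-decaying"):
            fit_persistence_length(corr, 1.0, fit_range=(1, 6))


class TestMeanSpacing:
    def test_rest_chain_exact(self, default_params):
        assert mean_spacing(init_chain(default_params, "linear")) == (
            pytest.approx(0.625, rel=1e-12))

    def test_two_frame_average(self):
        f1 = np.stack([np.arange(3) * 0.6, np.zeros(3)], axis=1)
        f2 = np.stack([np.arange(3) * 0.65, np.zeros(3)], axis=1)
        assert mean_spacing(np.stack([f1, f2])) == pytest.approx(0.625)

    def test_simulated_chain_near_rest_length(self, short_free_traj):
        # stiff bonds: fluctuation sqrt(kBT/k_b)/a = 10%, but the mean is
        # shifted only by the 2D radial measure (~sigma^2/(2a^2) ~ 0.5%)
        # plus the Euler-step variance bias; ~1% in total
        assert mean_spacing(short_free_traj) == pytest.approx(0.625, rel=0.02)


class TestComAndMsd:
    def test_uniform_translation_slope(self, default_params):
        base = init_chain(default_params, "linear").positions
        frames = np.stack([base + [0.3 * k, 0.0] for k in range(10)])
        x = com_series(frames, axis=0)
        np.testing.assert_allclose(np.diff(x), 0.3, rtol=1e-12)

    def test_static_chain_constant(self, default_params):
        base = init_chain(default_params, "circular").positions
        frames = np.repeat(base[None], 5, axis=0)
        assert np.ptp(com_series(frames, axis=0)) == 0.0
        assert com_series(frames, axis=1) == pytest.approx(0.0, abs=1e-12)

    def test_msd_constant_series_zero(self):
        lags, curve = msd(np.full(100, 3.7), max_lag=20)
        np.testing.assert_allclose(curve, 0.0, atol=1e-20)

    def test_msd_linear_ramp(self):
        v, dt = 3.0, 0.5
        t = np.arange(200) * dt
        lags, curve = msd(v * t, max_lag=30, dt=dt)
        np.testing.assert_allclose(curve, v**2 * lags**2, rtol=1e-10)

    def test_msd_nonnegative_and_zero_at_zero(self, rng):
        x = np.cumsum(rng.standard_normal(500))
        lags, curve = msd(x, max_lag=100)
        assert curve[0] == 0.0
        assert np.all(curve >= 0)

    def test_random_walk_slope(self, rng):
        D, dt = 0.13, 0.1
        n = 20000
        x = np.cumsum(rng.normal(0, math.sqrt(2 * D * dt), n))
        lags, curve = msd(x, max_lag=200, dt=dt)
        Dhat, _ = fit_diffusion_1d(lags, curve)
        # generous 3-sigma-ish bound for a single walk
        assert Dhat == pytest.approx(D, rel=0.1)


class TestDiffusionFit:
    def test_exact_curves(self):
        lags = np.linspace(0, 10, 50)
        assert fit_diffusion_1d(lags, 2 * 0.13 * lags)[0] == pytest.approx(
            0.13, rel=1e-12)
        assert fit_diffusion_1d(lags, 2 * lags)[0] == pytest.approx(
            1.0, rel=1e-12)

    def test_intercept_free(self):
        lags = np.linspace(0, 10, 50)
        D, _ = fit_diffusion_1d(lags, 2 * 0.5 * lags + 0.7,
                                fit_window=(lags[1], lags[-1]))
        assert D == pytest.approx(0.5, rel=1e-9)

    def test_negative_slope_is_error(self):
        lags = np.linspace(0, 10, 30)
        with pytest.raises(EstimationError, match="slope"):
            fit_diffusion_1d(lags, -lags)


class TestDriftAndMobility:
    def test_exact_line(self):
        t = np.linspace(0, 10, 60)
        assert drift_velocity(t, 3 * t) == pytest.approx(3.0, rel=1e-12)
        assert drift_velocity(t, np.full_like(t, 2.0)) == pytest.approx(
            0.0, abs=1e-12)

    def test_line_plus_white_noise(self, rng):
        t = np.linspace(0, 100, 2000)
        x = 3 * t + rng.normal(0, 0.5, t.size)
        v = drift_velocity(t, x)
        from scipy import stats as sps
        se = sps.linregress(t, x).stderr
        assert abs(v - 3.0) < 4 * se

    def test_mobility_single_point_ratio(self):
        assert fit_mobility([(0.01, 0.516)]) == pytest.approx(51.6, rel=1e-12)

    def test_mobility_exact_line(self):
        E = np.array([0.002, 0.005, 0.01])
        assert fit_mobility(list(zip(E, 51.6 * E))) == pytest.approx(
            51.6, rel=1e-12)

    def test_mobility_needs_nonzero_field(self):
        with pytest.raises(EstimationError):
            fit_mobility([(0.0, 0.1)])


class TestChargeAndManning:
    def test_effective_charge_study_values(self):
        # kBT mu / D with the study's mobility and diffusion constant
        q = effective_charge(51.6, 0.13, 300.0)
        assert q == pytest.approx(10.26, abs=0.01)

    def test_effective_charge_edge_cases(self):
        assert effective_charge(0.0, 0.5) == 0.0
        kbt_over_e = 8.617333262e-5 * 300
        assert effective_charge(0.13 / kbt_over_e, 0.13) == pytest.approx(
            1.0, rel=1e-12)
        with pytest.raises(ValueError):
            effective_charge(51.6, 0.0)

    def test_screening_fraction_values(self):
        assert screening_fraction(10.2, 19) == pytest.approx(0.463, abs=5e-4)
        assert screening_fraction(19, 19) == 0.0
        assert screening_fraction(0.0, 19) == 1.0

    @given(q=st.floats(0, 19), n=st.integers(1, 40))
    @settings(max_examples=40, deadline=None)
    def test_screening_identity(self, q, n):
        if q <= n:
            assert screening_fraction(q, n) + q / n == pytest.approx(
                1.0, rel=1e-12)

    def test_screening_clamped_with_warning(self):
        with pytest.warns(RuntimeWarning, match="clamped"):
            assert screening_fraction(25.0, 19) == 0.0

    def test_manning_study_value(self):
        assert manning_condensed_fraction(0.625, 0.71) == pytest.approx(
            0.1197, abs=5e-4)

    def test_manning_below_threshold_zero(self):
        assert manning_condensed_fraction(0.8, 0.71) == 0.0
        assert manning_condensed_fraction(0.71, 0.71) == 0.0

    def test_manning_xi_two(self):
        assert manning_condensed_fraction(0.355, 0.71) == pytest.approx(0.5)


class TestOccupancyProximity:
    def test_all_on_stripe(self, default_params, stripe_pattern):
        pos = np.stack([np.linspace(-5, 5, 20), np.zeros(20)], axis=1)
        counts = domain_occupancy(pos[None], stripe_pattern)
        assert tuple(counts[0]) == (0, 20)

    def test_all_off_stripe(self, stripe_pattern):
        d = stripe_pattern.smoothing_delta
        y0 = stripe_pattern.stripe_width_w / 2 + 10 * d
        pos = np.stack([np.linspace(-5, 5, 20), np.full(20, y0)], axis=1)
        counts = domain_occupancy(pos[None], stripe_pattern)
        assert tuple(counts[0]) == (20, 0)

    def test_counts_sum_to_n_beads(self, short_free_traj, stripe_pattern):
        counts = domain_occupancy(short_free_traj, stripe_pattern)
        assert np.all(counts.sum(axis=1) == short_free_traj.n_beads)

    def test_uniform_rejected(self, short_free_traj):
        with pytest.raises(ValueError):
            domain_occupancy(short_free_traj, SurfacePattern(geometry="uniform"))

    def test_proximity_cutoff_boundary(self):
        assert proximity_count([[0, 0]], [[0.34, 0]], cutoff=0.35) == 1
        assert proximity_count([[0, 0]], [[0.36, 0]], cutoff=0.35) == 0

    def test_proximity_matches_brute_force(self, rng):
        a = rng.uniform(0, 3, (50, 2))
        b = rng.uniform(0, 3, (50, 2))
        cutoff = 0.35
        brute = sum(
            1 for p in a
            if np.any(np.linalg.norm(b - p, axis=1) <= cutoff)
        )
        assert proximity_count(a, b, cutoff) == brute
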