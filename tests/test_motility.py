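"""MSD estimators, two-regime fits, displacement statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from swarmtrack.motility import (
    FitError,
    MSDCurve,
    displacement_stats,
    ensemble_msd,
    exponent_distribution,
    fit_crossover,
    fit_two_regime,
    furth_msd,
    msd_per_track,
)
from swarmtrack.synthgen import MotilityModelParams, simulate_fbm_trajectories
from swarmtrack.track import Trajectory, ground_truth_to_trajectories


def make_track(xy, dt=1.0, tid=0):
    xy = np.asarray(xy, dtype=float)
    return Trajectory(tid, np.arange(len(xy)), xy, dt)


def brute_force_msd(xy, dt, k_max):
    """Independent oracle: explicit double loop over all start times."""
    out = []
    for k in range(1, k_max + 1):
        acc = [
            np.sum((xy[t + k] - xy[t]) ** 2) for t in range(len(xy) - k)
        ]
        out.append((k * dt, float(np.mean(acc))))
    return out


class TestMsdPerTrack:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(5, 40)
            xy = rng.normal(size=(n, 2))
            curve = msd_per_track(make_track(xy, dt=0.5), max_lag_fraction=1.0)
            for (lag, expected), got_lag, got in zip(
                brute_force_msd(xy, 0.5, n - 1), curve.lags, curve.msd
            ):
                assert got_lag == pytest.approx(lag)
                assert got == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_oracle_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        xy = rng.uniform(-5, 5, size=(n, 2))
        curve = msd_per_track(make_track(xy), max_lag_fraction=1.0)
        oracle = brute_force_msd(xy, 1.0, n - 1)
        np.testing.assert_allclose(curve.msd, [m for _, m in oracle], atol=1e-10)

    def test_five_point_worked_example(self):
        xy = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2)]
        curve = msd_per_track(make_track(xy), max_lag_fraction=1.0)
        assert curve.msd[0] == pytest.approx(1.0)
        assert curve.msd[1] == pytest.approx(2.0)
        np.testing.assert_array_equal(curve.n_pairs, [4, 3, 2, 1])

    def test_ballistic_identity(self):
        v, dt = 0.7, 2.0  # µm/s; one step advances v * dt
        xy = np.column_stack([v * dt * np.arange(20), np.zeros(20)])
        curve = msd_per_track(make_track(xy, dt=dt), max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.msd, v**2 * curve.lags**2, rtol=1e-12)

    def test_stationary_track_zero(self):
        curve = msd_per_track(make_track(np.ones((10, 2))))
        assert np.all(curve.msd == 0)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            msd_per_track(make_track(np.zeros((1, 2))))


class TestEnsembleMsd:
    def test_identical_tracks_idempotent(self):
        rng = np.random.default_rng(1)
        xy = rng.normal(size=(30, 2))
        single = msd_per_track(make_track(xy))
        double = ensemble_msd([make_track(xy, tid=0), make_track(xy, tid=1)])
        np.testing.assert_allclose(double.msd, single.msd, rtol=1e-12)

    def test_ballistic_plus_stationary_pooling(self):
        v, n = 0.5, 21
        ballistic = make_track(np.column_stack([v * np.arange(n), np.zeros(n)]))
        still = make_track(np.zeros((n, 2)), tid=1)
        curve = ensemble_msd([ballistic, still], max_lag_fraction=1.0)
        np.testing.assert_allclose(curve.msd, v**2 * curve.lags**2 / 2, rtol=1e-12)

    def test_pooling_equals_weighted_mean_of_tracks(self):
        rng = np.random.default_rng(2)
        tracks = [
            make_track(rng.normal(size=(n, 2)), tid=i)
            for i, n in enumerate([12, 20, 33])
        ]
        ens = ensemble_msd(tracks, max_lag_fraction=0.5)
        per = [msd_per_track(t, max_lag_fraction=0.5) for t in tracks]
        for lag, msd in zip(ens.lags, ens.msd):
            num = den = 0.0
            for c in per:
                sel = np.isclose(c.lags, lag)
                if sel.any():
                    num += float(c.msd[sel][0] * c.n_pairs[sel][0])
                    den += float(c.n_pairs[sel][0])
            assert msd == pytest.approx(num / den, rel=1e-12)

    def test_brownian_cohort_matches_4dt(self):
        s = 0.25  # per-frame step sd; D = s² / (2 dt)
        params = MotilityModelParams(
            model="fbm", hurst=0.5, sigma_step=s, n_cells=10_000, n_frames=64,
            frame_interval=0.5, seed=6,
        )
        tracks = ground_truth_to_trajectories(simulate_fbm_trajectories(params))
        ens = ensemble_msd(tracks, max_lag_fraction=0.25)
        per_track = np.stack(
            [msd_per_track(t, max_lag_fraction=0.25).msd for t in tracks]
        )
        se = per_track.std(axis=0, ddof=1) / np.sqrt(len(tracks))
        d_coef = s**2 / (2 * 0.5)
        assert np.all(np.abs(ens.msd - 4 * d_coef * ens.lags) < 3 * se)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            ensemble_msd([])


class TestTwoRegimeFit:
    def power_law_curve(self, alpha=1.4, c=0.2, lags=None):
        lags = np.arange(1, 41) * 0.25 if lags is None else lags
        return MSDCurve(lags, c * lags**alpha, np.full(len(lags), 10), "ensemble")

    def test_exact_power_law_recovered(self):
        fit = fit_two_regime(self.power_law_curve(alpha=1.4), t_c=3.0)
        assert fit.alpha1 == pytest.approx(1.4, abs=1e-9)
        assert fit.alpha2 == pytest.approx(1.4, abs=1e-9)
        assert fit.r2_1 == pytest.approx(1.0)

    @pytest.mark.parametrize("t_c", [1.5, 3.0, 5.0])
    def test_power_law_alpha_independent_of_boundary(self, t_c):
        fit = fit_two_regime(self.power_law_curve(alpha=0.8), t_c=t_c)
        assert fit.alpha1 == pytest.approx(0.8, abs=1e-9)
        assert fit.alpha2 == pytest.approx(0.8, abs=1e-9)

    def test_furth_curve_regime_exponents(self):
        # frozen oracle: numerically fitting the analytic PRW MSD at lags
        # 0.25-25 s with t_c = 3 s gives alpha1 ~ 1.88, alpha2 ~ 1.36
        lags = np.arange(1, 101) * 0.25
        curve = MSDCurve(lags, furth_msd(lags, 0.2, 3.0), np.full(100, 10), "ensemble")
        fit = fit_two_regime(curve, t_c=3.0)
        assert fit.alpha1 == pytest.approx(1.8847, abs=1e-3)
        assert fit.alpha2 == pytest.approx(1.3575, abs=1e-3)
        assert 1.5 < fit.alpha1 < 2.0

    def test_too_few_lags_names_regime(self):
        curve = self.power_law_curve(lags=np.array([0.5, 1.0, 2.0, 4.0]))
        with pytest.raises(FitError, match="late"):
            fit_two_regime(curve, t_c=3.0)

    def test_free_boundary_on_furth_curve(self):
        lags = np.arange(1, 101) * 0.25
        curve = MSDCurve(lags, furth_msd(lags, 0.2, 3.0), np.full(100, 10), "ensemble")
        fit = fit_crossover(curve)
        assert 2.1 <= fit.t_c <= 3.9  # within 30% of the 3 s relaxation time
        assert fit.alpha1 > fit.alpha2


class TestDisplacementStats:
    def test_direct_enumeration(self):
        tracks = [
            make_track([(0, 0), (0, 0)], tid=0),
            make_track([(0, 0), (1, 0)], tid=1),
            make_track([(0, 0), (10, 0)], tid=2),
            make_track([(0, 0), (20, 0)], tid=3),
        ]
        stats = displacement_stats(tracks, body_length=4.0, factor=3.5, noise_floor=0.2)
        assert stats.p_large == pytest.approx(0.25)
        assert stats.zero_fraction == pytest.approx(0.25)
        assert stats.n_tracks == 4

    def test_all_stationary(self):
        tracks = [make_track(np.zeros((5, 2)), tid=i) for i in range(3)]
        stats = displacement_stats(tracks, 4.0, noise_floor=0.1)
        assert stats.p_large == 0.0 and stats.zero_fraction == 1.0

    def test_p_large_monotone_in_body_length(self):
        rng = np.random.default_rng(4)
        tracks = [
            make_track(np.cumsum(rng.normal(size=(50, 2)), axis=0), tid=i)
            for i in range(40)
        ]
        p1 = displacement_stats(tracks, 2.0).p_large
        p2 = displacement_stats(tracks, 4.0).p_large
        assert p2 <= p1

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(7)
        base = [np.cumsum(rng.normal(size=(30, 2)), axis=0) for _ in range(20)]
        theta = 0.83
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        shift = np.array([12.0, -7.0])
        orig = [make_track(xy, tid=i) for i, xy in enumerate(base)]
        moved = [make_track(xy @ rot.T + shift, tid=i) for i, xy in enumerate(base)]
        s1 = displacement_stats(orig, 3.0, noise_floor=0.5)
        s2 = displacement_stats(moved, 3.0, noise_floor=0.5)
        assert s1.p_large == s2.p_large
        assert s1.zero_fraction == s2.zero_fraction

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            displacement_stats([], 4.0)


class TestExponentDistribution:
    def fbm_tracks(self, hurst, n_cells=200, n_frames=400, seed=10):
        params = MotilityModelParams(
            model="fbm", hurst=hurst, sigma_step=0.2, n_cells=n_cells,
            n_frames=n_frames, frame_interval=0.5, seed=seed,
        )
        return ground_truth_to_trajectories(simulate_fbm_trajectories(params))

    def test_identical_ballistic_tracks_no_heterogeneity(self):
        xy = np.column_stack([0.4 * np.arange(60), np.zeros(60)])
        tracks = [make_track(xy, dt=0.5, tid=i) for i in range(10)]
        dist = exponent_distribution(tracks)
        np.testing.assert_allclose(dist.alpha1, 2.0, atol=1e-9)
        np.testing.assert_allclose(dist.alpha2, 2.0, atol=1e-9)
        assert dist.sd_alpha1 == pytest.approx(0.0, abs=1e-9)
        assert dist.sd_alpha2 == pytest.approx(0.0, abs=1e-9)

    def test_brownian_cohort_mean_alpha2_near_one(self):
        dist = exponent_distribution(self.fbm_tracks(hurst=0.5))
        assert abs(np.mean(dist.alpha2) - 1.0) < 0.1

    def test_immobile_mixture_widens_spread(self):
        pure = self.fbm_tracks(hurst=0.5, n_cells=100, seed=11)
        rng = np.random.default_rng(12)
        immobile = [
            make_track(rng.normal(0, 0.05, size=(400, 2)), dt=0.5, tid=100 + i)
            for i in range(100)
        ]
        mixed = pure[:50] + immobile[:50]
        d_pure = exponent_distribution(pure)
        d_mix = exponent_distribution(mixed)
        assert d_mix.sd_alpha2 > d_pure.sd_alpha2

    def test_unfittable_cohort_raises(self):
        tracks = [make_track(np.zeros((40, 2)), tid=i) for i in range(5)]
        with pytest.raises(FitError):
            exponent_distribution(tracks)
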