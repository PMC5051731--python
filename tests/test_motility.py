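import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from asterdrift.motility import (directionality, downsample, ensemble_msd,
                                 fit_distance_time, fit_lognormal_velocity,
                                 fit_msd_anomalous, fit_msd_drift,
                                 instantaneous_velocities, msd, radial_density,
                                 radial_profile)
from asterdrift.rwd import Trajectory


def make_track(times, positions, tid="t0", **kw):
    return Trajectory(track_id=tid, times=np.asarray(times, float),
                      positions=np.asarray(positions, float), **kw)


def linear_track(v=0.01, dt=210.0, n=30, angle=0.3):
    t = np.arange(n) * dt
    d = v * t
    return make_track(t, np.column_stack([d * math.cos(angle), d * math.sin(angle)]))


class TestDownsample:
    def test_count_on_fine_track(self):
        t = np.arange(0, 8000.1, 0.1)
        tr = make_track(t, np.zeros((len(t), 2)) + np.arange(len(t))[:, None] * 1e-4)
        ds = downsample(tr, 210.0)
        assert len(ds) <= 40
        assert ds.times[0] == tr.times[0] and ds.times[-1] == tr.times[-1]

    def test_identity_at_native_step(self):
        tr = linear_track(n=12)
        ds = downsample(tr, 210.0)
        assert np.array_equal(ds.times, tr.times)

    def test_two_point_track_unchanged(self):
        tr = make_track([0.0, 210.0], [[0, 0], [1, 1]])
        ds = downsample(tr, 500.0)
        assert len(ds) == 2

    def test_interval_below_native_rejected(self):
        with pytest.raises(ValueError):
            downsample(linear_track(), 10.0)


class TestVelocitiesAndChi:
    def test_straight_motion_speed(self):
        tr = make_track([0, 210.0], [[0, 0], [2.1, 0]])
        assert instantaneous_velocities(tr) == pytest.approx([0.01])

    def test_stationary_zeros(self):
        tr = make_track([0, 10, 20], np.ones((3, 2)))
        assert np.allclose(instantaneous_velocities(tr), 0.0)

    def test_straight_path_chi_one(self):
        assert directionality(linear_track()) == pytest.approx(1.0)

    def test_closed_path_chi_zero(self):
        tr = make_track([0, 1, 2], [[0, 0], [1, 0], [0, 0]])
        assert directionality(tr) == pytest.approx(0.0)

    def test_perpendicular_legs(self):
        tr = make_track([0, 1, 2], [[0, 0], [1, 0], [1, 1]])
        assert directionality(tr) == pytest.approx(math.sqrt(2) / 2)

    def test_zero_length_path_undefined(self):
        tr = make_track([0, 1], [[1, 1], [1, 1]])
        assert directionality(tr) is None

    @given(st.integers(0, 2 ** 31 - 1))
    def test_chi_bounds_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        tr = make_track(np.arange(n) * 10.0, np.cumsum(rng.normal(size=(n, 2)), axis=0))
        chi = directionality(tr)
        assert chi is None or 0.0 <= chi <= 1.0


class TestMsd:
    def test_matches_brute_force_double_loop(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 21))
            tr = make_track(np.arange(n) * 5.0, rng.normal(size=(n, 2)))
            curve = msd(tr)
            kmax = int(math.floor(0.75 * (n - 1)))
            for k in range(1, kmax + 1):
                acc = [np.sum((tr.positions[i + k] - tr.positions[i]) ** 2)
                       for i in range(n - k)]
                assert curve.msd[k - 1] == pytest.approx(np.mean(acc), rel=1e-12)
                assert curve.n_pairs[k - 1] == n - k

    def test_ballistic_exact(self):
        tr = linear_track(v=0.01)
        curve = msd(tr)
        assert np.allclose(curve.msd, (0.01 * curve.lags) ** 2, rtol=1e-9)

    def test_lag_cutoff(self):
        tr = linear_track(n=41)
        curve = msd(tr)
        assert curve.lags[-1] <= 0.75 * tr.duration + 1e-9


class TestFits:
    def test_drift_fit_exact_recovery(self):
        lags = np.arange(1, 30) * 210.0
        y = 4 * 0.006 * lags + (0.008 * lags) ** 2
        fit = fit_msd_drift(type("C", (), {"lags": lags, "msd": y, "n_pairs": None}))
        assert fit.D_eff == pytest.approx(0.006, rel=1e-4)
        assert fit.v_eff == pytest.approx(0.008, rel=1e-4)

    def test_drift_fit_degenerate(self):
        lags = np.arange(1, 10) * 10.0
        fit = fit_msd_drift(type("C", (), {"lags": lags, "msd": np.zeros(9),
                                           "n_pairs": None}))
        assert fit.D_eff == 0.0 and fit.v_eff == 0.0

    def test_anomalous_ballistic(self):
        lags = np.arange(1, 20) * 10.0
        v = 0.01
        curve = type("C", (), {"lags": lags, "msd": (v * lags) ** 2, "n_pairs": None})
        fit = fit_msd_anomalous(curve)
        assert fit.alpha == pytest.approx(2.0, abs=1e-6)
        assert fit.D_prime == pytest.approx(v ** 2 / 4, rel=1e-5)

    def test_anomalous_diffusive(self):
        lags = np.arange(1, 20) * 10.0
        curve = type("C", (), {"lags": lags, "msd": 4 * 0.006 * lags, "n_pairs": None})
        fit = fit_msd_anomalous(curve)
        assert fit.alpha == pytest.approx(1.0, abs=1e-6)
        assert fit.D_prime == pytest.approx(0.006, rel=1e-5)

    def test_anomalous_confined_walk_subdiffusive(self):
        # brute-force walk confined to a small disk: msd saturates, alpha < 1
        rng = np.random.default_rng(0)
        pos = np.zeros(2)
        out = [pos.copy()]
        for _ in range(4000):
            cand = pos + rng.normal(0, 0.3, 2)
            if np.hypot(*cand) < 2.0:
                pos = cand
            out.append(pos.copy())
        tr = make_track(np.arange(4001) * 1.0, np.array(out))
        fit = fit_msd_anomalous(msd(tr))
        assert fit.alpha < 0.8

    @pytest.mark.parametrize("n_true", [0.5, 1.0, 2.0, 4.0])
    def test_distance_time_recovery(self, n_true):
        t = np.arange(0, 4000.0, 100.0)
        d = 20.0 * t ** n_true / (1200.0 ** n_true + t ** n_true)
        ang = np.linspace(0, 0.5, len(t))
        tr = make_track(t, np.column_stack([d * np.cos(ang), d * np.sin(ang)]))
        fit = fit_distance_time(tr)
        assert fit.d_max == pytest.approx(20.0, rel=1e-3)
        assert fit.T_half == pytest.approx(1200.0, rel=1e-3)
        assert fit.n == pytest.approx(n_true, rel=1e-3)
        assert fit.mode == ("pulling" if n_true > 1 else "pushing")
        assert fit.reliable

    def test_distance_time_example(self):
        t = np.arange(0, 300.0, 10.0)
        d = 20.0 * t ** 2.5 / (30.0 ** 2.5 + t ** 2.5)
        tr = make_track(t, np.column_stack([d, np.zeros_like(d)]))
        fit = fit_distance_time(tr)
        assert fit.d_max == pytest.approx(20.0, rel=1e-2)
        assert fit.n == pytest.approx(2.5, rel=1e-2)
        assert fit.mode == "pulling"

    def test_distance_time_degenerate(self):
        tr = make_track(np.arange(5) * 10.0, np.zeros((5, 2)))
        with pytest.raises(ValueError):
            fit_distance_time(tr)


class TestLognormal:
    def test_recovery_against_moment_oracle(self):
        rng = np.random.default_rng(4)
        # draw from the lognormal whose linear mean/variance match the
        # reference motility scale
        target_mean, target_var = 8.8e-3, 4.57e-5
        s2 = math.log(1 + target_var / target_mean ** 2)
        mu = math.log(target_mean) - s2 / 2
        draws = rng.lognormal(mu, math.sqrt(s2), size=10000)
        mean, var = fit_lognormal_velocity(draws)
        # moment-matching oracle on the same draws
        assert mean == pytest.approx(np.mean(draws), rel=0.02)
        assert var == pytest.approx(np.var(draws), rel=0.2)
        assert mean == pytest.approx(target_mean, rel=0.05)

    def test_constant_speeds(self):
        mean, var = fit_lognormal_velocity(np.full(50, 0.01))
        assert mean == pytest.approx(0.01)
        assert var == pytest.approx(0.0, abs=1e-12)

    def test_requires_positive_sample(self):
        with pytest.raises(ValueError):
            fit_lognormal_velocity(np.zeros(50))


class TestProfilesAndDensity:
    def test_radial_chi_profile_straight_tracks(self):
        trajs = []
        for r0 in (12.0, 18.0, 24.0, 33.0):
            t = np.arange(6) * 210.0
            x = r0 - 0.005 * t
            trajs.append(make_track(t, np.column_stack([x, np.zeros_like(x)]),
                                    tid=f"r{r0}"))
        prof = radial_profile(trajs, r_cell=40.0, bin_width=5.0, measure="chi")
        assert np.allclose(prof["mean"], 1.0)

    def test_brownian_tracks_low_flat_chi(self):
        rng = np.random.default_rng(1)
        trajs = []
        for i in range(40):
            start = np.array([15.0 + (i % 4) * 5.0, 0.0])
            steps = rng.normal(0, 0.5, size=(40, 2))
            trajs.append(make_track(np.arange(41) * 210.0,
                                    start + np.vstack([[0, 0], np.cumsum(steps, 0)]),
                                    tid=f"b{i}"))
        prof = radial_profile(trajs, r_cell=40.0, bin_width=5.0, measure="chi")
        assert (prof["mean"] < 0.5).all()

    def test_bad_bin_width(self):
        with pytest.raises(ValueError):
            radial_profile([], 40.0, 0.0)

    def test_uniform_density_flat(self):
        rng = np.random.default_rng(2)
        r = 40.0 * np.sqrt(rng.uniform(size=40000))
        a = rng.uniform(0, 2 * math.pi, size=40000)
        pts = np.column_stack([r * np.cos(a), r * np.sin(a)])
        dens = radial_density(pts, 40.0, 5.0)
        expected = 1.0 / (math.pi * 40.0 ** 2)
        assert np.allclose(dens["density"], expected, rtol=0.1)

    def test_point_mass_density(self):
        pts = np.zeros((100, 2)) + 1.0
        dens = radial_density(pts, 40.0, 5.0)
        assert dens["count"].iloc[0] == 100
        assert dens["count"].iloc[1:].sum() == 0


def test_ensemble_msd_pools_tracks():
    t1 = linear_track(v=0.01, n=20)
    t2 = linear_track(v=0.01, n=12, angle=1.0)
    curve = ensemble_msd([t1, t2])
    assert np.allclose(curve.msd, (0.01 * curve.lags) ** 2, rtol=1e-9)
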