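"""Ensemble statistics: MSD, PSD, bouts, KS heterogeneity, classes, switching, variance."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from cellmotility import ensemble, simulate as sim
from cellmotility.ensemble import MSDCurve
from cellmotility.io import TrajectorySet
from cellmotility.kinematics import secant_velocities

from conftest import make_track


class TestMSD:
    def test_ballistic_identity(self, straight_track):
        """A constant-velocity track has MSD(m t_int) = (v m t_int)^2 exactly."""
        curve = ensemble.msd_curve(
            TrajectorySet([straight_track]), max_lag=7.5, n_boot=10, seed=0, min_tracks=1
        )
        v = 5.0 / 0.75  # µm/min
        np.testing.assert_allclose(curve.msd, (v * curve.lags) ** 2, rtol=1e-10)

    def test_fft_msd_matches_brute_force(self, random_walk_track):
        pos = random_walk_track.positions
        fast = ensemble._track_msd_fft(pos)
        N = len(pos)
        brute = np.array(
            [np.mean(np.sum((pos[m:] - pos[:-m]) ** 2, axis=1)) for m in range(1, N)]
        )
        np.testing.assert_allclose(fast, brute, rtol=1e-9)

    def test_rigid_motion_invariance(self, random_walk_track):
        pos = random_walk_track.positions
        theta = 0.83
        R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
        moved = make_track(pos @ R.T + [12.0, -7.0])
        a = ensemble._track_msd_fft(pos)
        b = ensemble._track_msd_fft(moved.positions)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_matches_closed_form_for_ou_ensemble(self, ou_ensemble):
        tracks, _ = ou_ensemble
        curve = ensemble.msd_curve(tracks, max_lag=20.0, n_boot=500, seed=3)
        theory = sim.theoretical_msd(curve.lags, 6.0, 2.0)
        inside = (theory >= curve.ci_low) & (theory <= curve.ci_high)
        # allow isolated excursions of a 95% band over ~27 correlated lags
        assert inside.mean() > 0.85

    def test_pure_noise_msd_is_4_sigma2(self):
        sigma = 1.0
        pop = sim.PopulationParams(
            n_cells=150,
            speed_law={"name": "fixed", "value": 0.0},
            coupling=sim.UPT(P0=1.0),
            duration=60.0,
            dt=9.0,
            sigma_loc=sigma,
            sample_interval=45.0,
            seed=17,
        )
        tracks, _ = sim.simulate_observed(pop)
        curve = ensemble.msd_curve(tracks, max_lag=10.0, n_boot=300, seed=18)
        assert np.all(curve.ci_low < 4 * sigma**2) and np.all(curve.ci_high > 4 * sigma**2 * 0.9)
        assert curve.msd.mean() == pytest.approx(4 * sigma**2, rel=0.05)

    def test_error_when_no_track_long_enough(self, straight_track):
        with pytest.raises(ValueError, match="longest available"):
            ensemble.msd_curve(TrajectorySet([straight_track]), max_lag=1000.0)

    def test_require_all_lags_filters_short_tracks(self, random_walk_track, straight_track):
        ts = TrajectorySet([random_walk_track, straight_track])  # 59 and 40 steps
        curve = ensemble.msd_curve(ts, max_lag=35 * 0.75, require_all_lags=True, n_boot=10, seed=0, min_tracks=1)
        assert np.all(curve.n_tracks == 2)  # straight track (40 steps) qualifies
        curve2 = ensemble.msd_curve(ts, max_lag=50 * 0.75, require_all_lags=True, n_boot=10, seed=0, min_tracks=1)
        assert np.all(curve2.n_tracks == 1)

    def test_bootstrap_bands_contain_point_estimate(self, ou_ensemble):
        tracks, _ = ou_ensemble
        sub = TrajectorySet(list(tracks.trajectories[:100]))
        curve = ensemble.msd_curve(sub, max_lag=15.0, n_boot=300, seed=6)
        assert np.all(curve.ci_low <= curve.msd) and np.all(curve.msd <= curve.ci_high)

    def test_track_order_invariance(self, ou_ensemble):
        tracks, _ = ou_ensemble
        sub = TrajectorySet(list(tracks.trajectories[:50]))
        rev = TrajectorySet(list(tracks.trajectories[:50])[::-1])
        a = ensemble.msd_curve(sub, max_lag=10.0, n_boot=10, seed=1)
        b = ensemble.msd_curve(rev, max_lag=10.0, n_boot=10, seed=1)
        np.testing.assert_allclose(a.msd, b.msd, rtol=1e-12)


class TestMSDFit:
    @staticmethod
    def _exact_curve(S=6.0, P=2.0, sigma2=0.5, n=40):
        lags = np.arange(1, n) * 0.75
        msd = sim.theoretical_msd(lags, S, P) + sigma2
        return MSDCurve(
            lags=lags,
            msd=msd,
            ci_low=msd * 0.99,
            ci_high=msd * 1.01,
            n_tracks=np.full(len(lags), 100),
            t_int=45.0,
        )

    def test_exact_curve_recovered_below_1pct(self):
        fit = ensemble.fit_msd(self._exact_curve())
        assert fit.S == pytest.approx(6.0, rel=0.01)
        assert fit.P == pytest.approx(2.0, rel=0.01)
        assert fit.sigma2 == pytest.approx(0.5, rel=0.01)

    def test_zero_offset_nested_limit(self):
        fit = ensemble.fit_msd(self._exact_curve(sigma2=0.0))
        curve = self._exact_curve(sigma2=0.0)
        assert fit.sigma2 < 0.01 * curve.msd[0]

    def test_simulated_ensemble_recovery_within_10pct(self, ou_ensemble):
        tracks, _ = ou_ensemble
        curve = ensemble.msd_curve(tracks, max_lag=20.0, n_boot=400, seed=5)
        fit = ensemble.fit_msd(curve)
        assert fit.S == pytest.approx(6.0, rel=0.10)
        assert fit.P == pytest.approx(2.0, rel=0.10)

    def test_too_few_lags_rejected(self):
        c = self._exact_curve(n=4)
        with pytest.raises(ensemble.FitError, match="5 lags"):
            ensemble.fit_msd(c)


class TestPSD:
    def test_parseval_identity_random_tracks(self):
        """Per-track spectrum sums to the mean squared speed, <= 1e-9 relative."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 400)
            vel = rng.normal(0, 5, size=(n, 2))
            psd = ensemble._track_psd(vel, 400)
            msq = np.mean(np.sum(vel**2, axis=1))
            assert abs(psd.sum() - msq) <= 1e-9 * msq

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(1)
        tracks = []
        for i in range(200):
            # iid Gaussian velocities: integrate to positions
            vel = rng.normal(0, 4, size=(80, 2))
            pos = np.concatenate([[[0, 0]], np.cumsum(vel * 0.75, axis=0)])
            tracks.append(make_track(pos, track_id=f"t{i}"))
        curve = ensemble.velocity_psd(TrajectorySet(tracks))
        ok = curve.frequencies > 0
        slope = np.polyfit(np.log10(curve.frequencies[ok]), np.log10(curve.psd[ok]), 1)[0]
        assert abs(slope) < 0.05

    def test_piecewise_exact_two_segment_recovery(self):
        freqs = np.logspace(-2.5, -0.2, 60)
        x = np.log10(freqs)
        b, s1, s2 = x[25], -0.1, -2.0  # breakpoint on an observed frequency
        y = 1.0 + np.where(x < b, s1 * (x - b), s2 * (x - b))
        curve = ensemble.PSDCurve(
            frequencies=freqs, psd=10**y, n_tracks=1, pad_to=400, t_int=45.0
        )
        fit = ensemble.fit_psd_piecewise(curve)
        assert fit.slope_low == pytest.approx(s1, abs=1e-6)
        assert fit.slope_high == pytest.approx(s2, abs=1e-6)
        assert math.log10(fit.breakpoint_freq) == pytest.approx(b, abs=1e-9)
        assert not fit.degenerate

    def test_piecewise_single_slope_flagged(self):
        freqs = np.logspace(-2.5, -0.2, 60)
        curve = ensemble.PSDCurve(
            frequencies=freqs, psd=freqs**-1.5, n_tracks=1, pad_to=400, t_int=45.0
        )
        fit = ensemble.fit_psd_piecewise(curve)
        assert fit.degenerate
        assert fit.slope_low == pytest.approx(fit.slope_high, abs=1e-6)

    def test_ou_spectrum_lorentzian_shape(self, ou_ensemble):
        """Flat at low frequency, slope -> -2 at high, knee near 1/(2 pi P)."""
        tracks, _ = ou_ensemble
        curve = ensemble.velocity_psd(tracks)
        fit = ensemble.fit_psd_piecewise(curve)
        assert -0.3 < fit.slope_low < 0.3
        assert -2.5 < fit.slope_high < -1.5
        knee = 1.0 / (2 * math.pi * 2.0)
        assert knee / 2 < fit.breakpoint_freq < knee * 2


class TestBoutDistribution:
    @staticmethod
    def _tracks_from_bouts(bouts, per_track=90):
        tracks = []
        for k, i in enumerate(range(0, len(bouts) - per_track + 1, per_track)):
            b = bouts[i : i + per_track]
            x = np.concatenate([[0.0], np.cumsum(b * np.resize([1.0, -1.0], len(b)))])
            tracks.append(
                make_track(np.column_stack([x, np.zeros(len(x))]), track_id=f"t{k}")
            )
        return TrajectorySet(tracks)

    @pytest.mark.parametrize("beta_true,lo,hi", [(1.0, 0.95, 1.05), (0.9, 0.85, 0.95)])
    def test_stretch_parameter_recovery(self, beta_true, lo, hi):
        """Samples with density ~ exp(-x^beta) recover beta within the band."""
        rng = np.random.default_rng(2)
        x = ss.gengamma(a=1 / beta_true, c=beta_true).rvs(30_000, random_state=rng)
        fit = ensemble.bout_distribution(self._tracks_from_bouts(x))
        assert lo <= fit.beta_stretch <= hi

    def test_fewer_bouts_than_bins_warns_and_reduces(self):
        rng = np.random.default_rng(3)
        ts = self._tracks_from_bouts(rng.exponential(size=10), per_track=10)
        with pytest.warns(UserWarning, match="bouts"):
            fit = ensemble.bout_distribution(ts, n_bins=25)
        assert fit.n_bouts == 10


class TestKSHeterogeneity:
    @staticmethod
    def _iid_population(n_tracks=300, steps=120, mix=False, seed=0):
        """Walkers whose secant speeds are iid draws (white-noise velocity limit)."""
        rng = np.random.default_rng(seed)
        tracks = []
        for i in range(n_tracks):
            scale = 1.0 if not mix or i % 2 == 0 else 5.0
            vel = rng.normal(0, scale, size=(steps, 2))
            pos = np.concatenate([[[0, 0]], np.cumsum(vel * 0.75, axis=0)])
            tracks.append(make_track(pos, track_id=f"t{i}"))
        return TrajectorySet(tracks)

    def test_type_one_error_calibrated_under_iid_null(self):
        res = ensemble.ks_heterogeneity(self._iid_population(), "speed", alpha=0.01)
        # fraction -> alpha within ~2 binomial SEs at n=300
        assert res.fraction_flagged <= 0.01 + 2 * math.sqrt(0.01 * 0.99 / 300) + 1e-9

    def test_mixture_power(self):
        res = ensemble.ks_heterogeneity(self._iid_population(mix=True), "speed", alpha=0.01)
        assert res.fraction_flagged > 0.8

    def test_single_track_against_own_pool(self):
        ts = self._iid_population(n_tracks=1, steps=400)
        pool = secant_velocities(ts[0]).speeds
        cdf = ensemble.percentile_cdf(pool)
        p = ss.kstest(pool, cdf).pvalue
        assert p > 0.9

    def test_bh_correction_is_more_conservative(self):
        ts = self._iid_population(n_tracks=100, seed=5)
        raw = ensemble.ks_heterogeneity(ts, "speed", alpha=0.05)
        bh = ensemble.ks_heterogeneity(ts, "speed", alpha=0.05, correction="bh")
        assert bh.fraction_flagged <= raw.fraction_flagged


class TestSpeedClasses:
    def test_ten_tracks_five_classes_two_each(self):
        rng = np.random.default_rng(4)
        tracks = []
        for i in range(10):
            vel = rng.normal(0, 1 + i, size=(40, 2))
            pos = np.concatenate([[[0, 0]], np.cumsum(vel * 0.75, axis=0)])
            tracks.append(make_track(pos, track_id=f"t{i}"))
        table = ensemble.speed_class_analysis(TrajectorySet(tracks), n_boot=20, seed=0)
        counts = table.assignments.groupby("speed_class").size()
        assert list(counts) == [2, 2, 2, 2, 2]

    def test_spc_turning_monotone_across_classes(self, spc_population):
        tracks, _ = spc_population
        table = ensemble.speed_class_analysis(tracks, n_boot=50, seed=1)
        mean_angle = (
            table.angle_hist.assign(w=lambda d: d.density * d.angle_rad)
            .groupby("speed_class")
            .apply(lambda d: np.sum(d.w) / np.sum(d.density), include_groups=False)
        )
        assert all(np.diff(mean_angle.to_numpy()) < 0)  # faster class turns less

    def test_upt_conditioned_turning_coincides(self, ou_ensemble):
        tracks, _ = ou_ensemble
        sub = TrajectorySet(list(tracks.trajectories[:150]))
        table = ensemble.speed_class_analysis(sub, n_boot=200, seed=2)
        t = table.conditioned_turning.dropna()
        # identical walkers: class curves share the underlying relationship, so
        # per-class means at comparable local speeds overlap within CIs
        merged = t.groupby("speed_class")["mean_cos"].mean()
        assert merged.max() - merged.min() < 0.15


class TestSpeedSwitching:
    def test_static_speeds_high_flat_rho_null_straddles_zero(self, spc_population):
        tracks, _ = spc_population
        sw = ensemble.speed_switching(tracks, n_perm=200, n_boot=200, seed=3)
        assert (sw.table.rho > 0.8).all()
        assert (sw.table.null_low < 0).all() and (sw.table.null_high > 0).all()

    def test_switching_population_decays(self):
        pop = sim.PopulationParams(
            n_cells=150, duration=160.0, dt=9.0, sample_interval=45.0,
            switching_rate=1 / 60.0, seed=6,
        )
        tracks, _ = sim.simulate_observed(pop)
        sw = ensemble.speed_switching(tracks, n_perm=50, n_boot=50, seed=7)
        rho = sw.table.set_index("delta_min").rho
        assert rho.loc[117.0] < rho.loc[19.5]

    def test_permuted_speeds_within_null_band(self, spc_population):
        tracks, _ = spc_population
        # destroy identity by shuffling positions across tracks blockwise:
        # simplest faithful null input: assign each track a random other's steps per block
        rng = np.random.default_rng(8)
        trs = list(tracks.trajectories)
        n_steps = min(tr.n_steps for tr in trs)
        speeds = np.stack([secant_velocities(tr).velocities[:n_steps] for tr in trs])
        block = 26  # 19.5 min of 45 s steps
        for b in range(0, n_steps - block + 1, block):
            perm = rng.permutation(len(trs))
            speeds[:, b : b + block] = speeds[perm, b : b + block]
        rebuilt = []
        for i, v in enumerate(speeds):
            pos = np.concatenate([[[0, 0]], np.cumsum(v * 0.75, axis=0)])
            rebuilt.append(make_track(pos, track_id=f"r{i}"))
        sw = ensemble.speed_switching(TrajectorySet(rebuilt), n_perm=200, n_boot=50, seed=9)
        # one draw against a 95% envelope across correlated lags: demand that
        # the correlation signal is gone, and most points sit inside the band
        assert sw.table.rho.abs().max() < 0.12
        ok = (sw.table.rho >= sw.table.null_low) & (sw.table.rho <= sw.table.null_high)
        assert ok.mean() >= 0.6

    def test_all_tracks_too_short_error(self, straight_track):
        with pytest.raises(ValueError, match="blocks"):
            ensemble.speed_switching(TrajectorySet([straight_track]), n_perm=5, n_boot=5)


class TestVarianceDecomposition:
    @staticmethod
    def _population(f, sd, n=300, k=80, seed=11):
        rng = np.random.default_rng(seed)
        S = rng.lognormal(np.log(5), 0.5, n)
        cos = [f(S[i]) + rng.normal(0, sd, k) for i in range(n)]
        df = pd.DataFrame(
            {
                "mean_speed": S,
                "mean_cos": [c.mean() for c in cos],
            }
        )
        return df, cos, S

    def test_deterministic_relationship_gives_frac_speed_near_one(self):
        df, cos, S = self._population(lambda s: 0.2 + 0.05 * s, sd=0.02, k=2000)
        vd = ensemble.variance_decomposition_turning(df, cos)
        assert vd.frac_speed > 0.95

    def test_null_relationship_gives_frac_speed_near_zero(self):
        df, cos, S = self._population(lambda s: 0.5, sd=0.3)
        vd = ensemble.variance_decomposition_turning(df, cos)
        assert vd.frac_speed < 0.1
        assert vd.frac_stochastic > 0.8

    def test_constructed_shares_recovered_within_10pct(self):
        sd, k = 0.25, 80
        f = lambda s: 0.15 + 0.05 * np.minimum(s, 8.0)
        df, cos, S = self._population(f, sd=sd, k=k, n=500)
        vd = ensemble.variance_decomposition_turning(df, cos)
        Vs_true = np.var(f(S), ddof=1)
        Vst_true = sd**2 / (k - 1)  # mean cosine sampling variance at fixed k
        tot = Vs_true + Vst_true
        assert vd.frac_speed == pytest.approx(Vs_true / tot, rel=0.10)
        assert vd.frac_stochastic == pytest.approx(Vst_true / tot, rel=0.10)

    def test_degenerate_speeds_error(self):
        df, cos, _ = self._population(lambda s: 0.5, sd=0.1, n=30)
        df["mean_speed"] = 5.0
        with pytest.raises(ValueError, match="degenerate|distinct"):
            ensemble.variance_decomposition_turning(df, cos)


class TestVarianceBySample:
    @staticmethod
    def _summaries(means, n_per=40, v=1.0, seed=13):
        rng = np.random.default_rng(seed)
        rows = []
        for s, mu in enumerate(means):
            for _ in range(n_per):
                rows.append({"sample_id": f"f{s}", "mean_speed": rng.normal(mu, math.sqrt(v))})
        return pd.DataFrame(rows)

    def test_identical_distributions_low_r2(self):
        df = self._summaries([5.0] * 16)
        assert ensemble.variance_by_sample(df) < 0.1

    def test_constant_within_sample_r2_one(self):
        df = self._summaries([3.0, 5.0, 9.0], v=1e-12)
        assert ensemble.variance_by_sample(df) == pytest.approx(1.0, abs=1e-6)

    def test_two_sample_closed_form(self):
        delta, v = 2.0, 1.0
        df = self._summaries([5.0, 5.0 + delta], n_per=4000, v=v)
        expected = delta**2 / (delta**2 + 4 * v)
        assert ensemble.variance_by_sample(df) == pytest.approx(expected, abs=0.02)

    def test_single_sample_error(self):
        df = self._summaries([5.0])
        with pytest.raises(ValueError, match="2 samples"):
            ensemble.variance_by_sample(df)
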