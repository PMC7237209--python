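"""Population-level trajectory statistics.

All ensemble statistics average a per-trajectory quantity across tracks and
attach 95% confidence intervals from a bootstrap whose resampling unit is the
trajectory. All stochastic procedures (bootstraps, permutation nulls) take an
explicit seed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import optimize, stats
from scipy.interpolate import UnivariateSpline

from .io import TrajectorySet
from .kinematics import MotilitySummary, secant_velocities, turn_angles, bout_lengths

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """A model fit failed to converge; carries the attempted initialization."""


# ---------------------------------------------------------------------------
# bootstrap helpers
# ---------------------------------------------------------------------------

def _bootstrap_rowmean_ci(M: np.ndarray, n_boot: int, rng, ci: float = 0.95):
    """Percentile CI of the column-wise nanmean of ``M`` under row resampling."""
    n = M.shape[0]
    out = np.empty((n_boot, M.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            out[b] = np.nanmean(M[idx], axis=0)
    q = 100 * (1 - ci) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo, hi = np.nanpercentile(out, [q, 100 - q], axis=0)
    return lo, hi


def _rank_bins(values: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split indices into ``n_bins`` equal-count groups ordered by value.

    Ties are broken by stable input order, so the partition is deterministic.
    """
    order = np.argsort(values, kind="stable")
    return [np.asarray(g) for g in np.array_split(order, n_bins)]


# ---------------------------------------------------------------------------
# mean squared displacement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MSDCurve:
    """Ensemble MSD vs lag with bootstrap 95% bands.

    ``lags`` in minutes, ``msd`` in µm²; ``n_tracks`` counts the trajectories
    entering each lag. ``per_track`` holds the (n_tracks, n_lags) matrix of
    per-trajectory time-averaged MSDs (NaN where a track is too short).
    """

    lags: np.ndarray
    msd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_tracks: np.ndarray
    t_int: float
    per_track: np.ndarray = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_min": self.lags,
                "msd_um2": self.msd,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "n_tracks": self.n_tracks,
            }
        )


@dataclass(frozen=True)
class MSDFit:
    """Persistent-random-walk fit of an MSD curve.

    ``S`` (µm/min), ``P`` (min) and a static noise offset ``sigma2`` (µm²),
    with the parameter covariance from the weighted log-space fit.
    """

    S: float
    P: float
    sigma2: float
    covariance: np.ndarray


def _track_msd_fft(pos: np.ndarray) -> np.ndarray:
    """Time-averaged MSD of one track at all lags 1..N-1 (FFT algorithm)."""
    N = len(pos)
    D = np.einsum("ij,ij->i", pos, pos)
    nfft = sp_fft.next_fast_len(2 * N)
    S2 = np.zeros(N)
    for c in range(pos.shape[1]):
        f = np.fft.rfft(pos[:, c], nfft)
        S2 += np.fft.irfft(f * np.conj(f), nfft)[:N]
    Dsum = np.concatenate(([0.0], np.cumsum(D)))
    m = np.arange(1, N)
    S1 = Dsum[N - m] + (Dsum[N] - Dsum[m])
    return (S1 - 2.0 * S2[1:]) / (N - m)


def msd_curve(
    tracks: TrajectorySet,
    max_lag: float | None = None,
    require_all_lags: bool = False,
    n_boot: int = 1000,
    seed: int | None = None,
    min_tracks: int = 30,
) -> MSDCurve:
    """Ensemble MSD: per-track time-averaged MSDs averaged across tracks.

    The per-track MSD at lag m·t_int averages the squared displacement over
    all start points; the ensemble curve averages per-track MSDs. The lag grid
    is every integer multiple of t_int up to ``max_lag`` (minutes); by default
    ``max_lag`` is the longest lag for which at least ``min_tracks`` tracks
    (or all tracks, if fewer) qualify. With ``require_all_lags`` only tracks
    containing every lag of the grid are used.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    t_int = tracks.t_int
    t_int_min = t_int / 60.0
    steps = np.array([tr.n_steps for tr in tracks])
    if max_lag is None:
        need = min(min_tracks, len(tracks))
        max_m = int(np.sort(steps)[::-1][need - 1])
    else:
        max_m = int(round(max_lag * 60.0 / t_int))
        if steps.max() < max_m:
            raise ValueError(
                f"no track long enough for lag {max_lag} min; longest available is "
                f"{steps.max() * t_int_min} min"
            )
    max_m = max(max_m, 1)
    M = np.full((len(tracks), max_m), np.nan)
    for i, tr in enumerate(tracks):
        m = min(tr.n_steps, max_m)
        M[i, :m] = _track_msd_fft(tr.positions)[:m]
    if require_all_lags:
        keep = ~np.isnan(M).any(axis=1)
        if not keep.any():
            raise ValueError("require_all_lags: no track contains every lag")
        M = M[keep]
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        msd = np.nanmean(M, axis=0)
    lo, hi = _bootstrap_rowmean_ci(M, n_boot, rng)
    return MSDCurve(
        lags=np.arange(1, max_m + 1) * t_int_min,
        msd=msd,
        ci_low=lo,
        ci_high=hi,
        n_tracks=np.sum(~np.isnan(M), axis=0),
        t_int=t_int,
        per_track=M,
    )


def _msd_model(tau, S, P, sigma2):
    return 2.0 * S**2 * P * tau * (1.0 + (P / tau) * np.expm1(-tau / P)) + sigma2


def fit_msd(curve: MSDCurve) -> MSDFit:
    """Weighted log-space fit of the persistent-random-walk MSD model.

    Fits MSD(tau) = 2 S² P tau (1 + (P/tau)(e^(-tau/P) - 1)) + sigma² in log
    space, weighted by the log-scale half-widths of the bootstrap bands.
    """
    ok = (
        np.isfinite(curve.msd)
        & (curve.msd > 0)
        & np.isfinite(curve.ci_low)
        & np.isfinite(curve.ci_high)
        & (curve.ci_low > 0)
    )
    if ok.sum() < 5:
        raise FitError("need at least 5 lags with finite positive CIs")
    tau, y = curve.lags[ok], curve.msd[ok]
    sig = (np.log(curve.ci_high[ok]) - np.log(curve.ci_low[ok])) / (2 * 1.96)
    sig = np.maximum(sig, 1e-6)
    S0 = math.sqrt(y[0]) / tau[0]
    D_long = y[-1] / (4 * tau[-1])
    P0 = float(np.clip(2.0 * D_long / max(S0**2, 1e-12), tau[0] / 2, tau[-1]))
    p0 = (S0, P0, y[0] * 0.01)

    def logmodel(tau, S, P, sigma2):
        return np.log(_msd_model(tau, S, P, sigma2))

    try:
        popt, pcov = optimize.curve_fit(
            logmodel,
            tau,
            np.log(y),
            p0=p0,
            sigma=sig,
            absolute_sigma=True,
            bounds=([1e-9, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - pathological inputs
        raise FitError(f"MSD fit did not converge from p0={p0}: {err}") from err
    return MSDFit(S=float(popt[0]), P=float(popt[1]), sigma2=float(popt[2]), covariance=pcov)


# ---------------------------------------------------------------------------
# velocity power spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PSDCurve:
    """Trajectory-averaged velocity power spectrum.

    ``frequencies`` in cycles/min for k = 0..N/2 (N = pad length); the
    normalization makes each track's spectrum sum to its mean squared speed.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    n_tracks: int
    pad_to: int
    t_int: float


def _track_psd(vel: np.ndarray, pad_to: int) -> np.ndarray:
    """Spectrum of one track's secant velocities, zero-padded to ``pad_to``.

    PSD(k) = (1/N²)(N/N_m) Σ_i [|v_i(k)|² + |v_i(N-k)|²] for interior k and
    the single-term version at k = 0 and k = N/2; by Parseval the values for
    k = 0..N/2 sum to the track's mean squared speed (1/N_m) Σ|v|².
    """
    N = pad_to
    Nm = len(vel)
    F = np.fft.rfft(vel, n=N, axis=0)  # k = 0..N/2
    power = np.abs(F) ** 2  # (N/2+1, 2)
    w = np.full(N // 2 + 1, 2.0)
    w[0] = 1.0
    if N % 2 == 0:
        w[-1] = 1.0
    return w * power.sum(axis=1) / (N * Nm)


def velocity_psd(tracks: TrajectorySet, pad_to: int = 400) -> PSDCurve:
    """Velocity power spectrum averaged over trajectories.

    Secant velocities of each track are zero-padded to ``pad_to`` timesteps
    (tracks longer than the pad are truncated, with a warning) and the
    per-track spectra are averaged with equal weight per trajectory.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    t_int = tracks.t_int
    acc = np.zeros(pad_to // 2 + 1)
    n_truncated = 0
    for tr in tracks:
        vel = secant_velocities(tr).velocities
        if len(vel) > pad_to:
            vel = vel[:pad_to]
            n_truncated += 1
        acc += _track_psd(vel, pad_to)
    if n_truncated:
        warnings.warn(f"velocity_psd: truncated {n_truncated} tracks to {pad_to} steps")
    freqs = np.arange(pad_to // 2 + 1) / (pad_to * t_int / 60.0)  # cycles/min
    return PSDCurve(
        frequencies=freqs, psd=acc / len(tracks), n_tracks=len(tracks), pad_to=pad_to, t_int=t_int
    )


@dataclass(frozen=True)
class PiecewiseFit:
    """Continuous two-segment linear fit of a spectrum in log-log space."""

    breakpoint_freq: float
    slope_low: float
    slope_high: float
    degenerate: bool


def fit_psd_piecewise(curve: PSDCurve, min_points_per_side: int = 3) -> PiecewiseFit:
    """Two-segment log-log fit with the breakpoint chosen by least squares.

    The candidate breakpoints are the observed positive frequencies; for each
    the continuous hinge model is linear and solved exactly, and the candidate
    with minimal residual sum of squares wins. A fit whose two slopes agree to
    1e-6, or whose breakpoint lands on the boundary of the grid, is flagged
    degenerate.
    """
    ok = (curve.frequencies > 0) & (curve.psd > 0)
    if ok.sum() < 8:
        raise ValueError("need at least 8 positive-frequency points")
    x = np.log10(curve.frequencies[ok])
    y = np.log10(curve.psd[ok])
    best = None
    cands = x[min_points_per_side:-min_points_per_side]
    for b in cands:
        left = np.minimum(x - b, 0.0)
        right = np.maximum(x - b, 0.0)
        A = np.column_stack([np.ones_like(x), left, right])
        coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(res[0]) if len(res) else float(np.sum((A @ coef - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, b, coef)
    _, b, coef = best
    degenerate = bool(
        abs(coef[1] - coef[2]) < 1e-6 or b == cands[0] or b == cands[-1]
    )
    if degenerate:
        logger.info("fit_psd_piecewise: degenerate (single-slope or boundary) spectrum")
    return PiecewiseFit(
        breakpoint_freq=float(10**b),
        slope_low=float(coef[1]),
        slope_high=float(coef[2]),
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# bout-length distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutDistribution:
    """Distribution of normalized bout lengths with stretched-exponential fit.

    Bouts are pooled across trajectories and binned on percentile bins; each
    bin's x location is the mean of the points it contains and densities are
    normalized by bin width. The fit is f(x) = A exp(-gamma x^beta).
    """

    bin_centers: np.ndarray
    densities: np.ndarray
    n_bouts: int
    A: float
    gamma: float
    beta_stretch: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bout_norm": self.bin_centers, "density": self.densities})


def bout_distribution(tracks: TrajectorySet, n_bins: int = 25) -> BoutDistribution:
    """Pooled normalized-bout histogram and stretched-exponential fit."""
    pooled = [bout_lengths(tr) for tr in tracks]
    bouts = np.concatenate([b for b in pooled if len(b)]) if pooled else np.empty(0)
    if len(bouts) == 0:
        raise ValueError("no bouts in input tracks")
    if len(bouts) < n_bins:
        warnings.warn(f"only {len(bouts)} bouts; reducing bins from {n_bins}")
        n_bins = max(2, len(bouts) // 2)
    edges = np.unique(np.percentile(bouts, np.linspace(0, 100, n_bins + 1)))
    dens, edges = np.histogram(bouts, bins=edges, density=True)
    which = np.clip(np.searchsorted(edges, bouts, side="right") - 1, 0, len(dens) - 1)
    centers = np.array([bouts[which == i].mean() for i in range(len(dens))])
    ok = dens > 0
    # the top percentile bin spans out to the sample maximum, so its
    # width-averaged density badly understates the density at the bin's mean
    # point; it is kept in the table but excluded from the fit
    ok[-1] = False
    x, logy = centers[ok], np.log(dens[ok])

    def model(x, logA, gamma, beta):
        return logA - gamma * x**beta

    p0 = (float(logy.max()), 1.0, 1.0)
    try:
        popt, _ = optimize.curve_fit(
            model, x, logy, p0=p0, bounds=([-np.inf, 1e-9, 0.05], [np.inf, np.inf, 2.0]),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover
        raise FitError(f"stretched-exponential fit failed from p0={p0}: {err}") from err
    return BoutDistribution(
        bin_centers=centers,
        densities=dens,
        n_bouts=len(bouts),
        A=float(np.exp(popt[0])),
        gamma=float(popt[1]),
        beta_stretch=float(popt[2]),
    )


# ---------------------------------------------------------------------------
# KS heterogeneity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    """Per-track KS tests against the pooled distribution."""

    fraction_flagged: float
    table: pd.DataFrame  # track_id, sample_id, n, p_value, flagged
    statistic: str
    alpha: float


def percentile_cdf(pool: np.ndarray, n_bins: int = 25):
    """Continuous CDF from cumulative frequency over percentile bins.

    The pooled CDF is evaluated at ``n_bins + 1`` percentile knots and
    linearly interpolated between them, mirroring a coarse but smooth
    empirical CDF estimate.
    """
    levels = np.linspace(0.0, 1.0, n_bins + 1)
    knots = np.quantile(pool, levels)
    knots = np.maximum.accumulate(knots)
    return lambda v: np.interp(v, knots, levels, left=0.0, right=1.0)


def ks_heterogeneity(
    tracks: TrajectorySet,
    statistic: str = "speed",
    alpha: float = 0.01,
    n_cdf_bins: int = 25,
    correction: str = "none",
) -> KSResult:
    """Fraction of tracks whose per-step statistic rejects the pooled CDF.

    The pooled empirical CDF of secant speeds (or folded turn angles) is built
    from percentile bins with linear interpolation and treated as fixed; each
    track's values are tested against it with a two-sided one-sample KS test.
    ``correction="bh"`` applies Benjamini-Hochberg before thresholding
    (the default thresholds raw p-values at ``alpha``).
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    per_track = []
    for tr in tracks:
        steps = secant_velocities(tr)
        if statistic == "speed":
            vals = steps.speeds
        elif statistic == "turn_angle":
            vals = turn_angles(steps).angles
        else:
            raise ValueError(f"unknown statistic {statistic!r}")
        per_track.append((tr.track_id, tr.sample_id, vals))
    pool = np.concatenate([v for _, _, v in per_track])
    cdf = percentile_cdf(pool, n_cdf_bins)
    rows = []
    for track_id, sample_id, vals in per_track:
        if len(vals) == 0:
            continue
        p = float(stats.kstest(vals, cdf).pvalue)
        rows.append({"track_id": track_id, "sample_id": sample_id, "n": len(vals), "p_value": p})
    table = pd.DataFrame(rows)
    pvals = table["p_value"].to_numpy()
    if correction == "bh":
        table["p_adjusted"] = stats.false_discovery_control(pvals, method="bh")
        table["flagged"] = table["p_adjusted"] < alpha
    elif correction == "none":
        table["flagged"] = table["p_value"] < alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return KSResult(
        fraction_flagged=float(table["flagged"].mean()),
        table=table,
        statistic=statistic,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# speed classes and conditioned turning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeedClassTable:
    """Speed-class (quantile-group) turning statistics.

    ``assignments``: per-track class index (0 = slowest); ``angle_hist``:
    per-class folded turn-angle densities with bootstrap bands;
    ``conditioned_turning``: per-class mean turn cosine vs binned local speed.
    """

    assignments: pd.DataFrame
    class_speeds: pd.DataFrame
    angle_hist: pd.DataFrame
    conditioned_turning: pd.DataFrame
    n_classes: int


def _pooled_angle_hist(turns_list, edges):
    pooled = np.concatenate([t for t in turns_list if len(t)]) if turns_list else np.empty(0)
    if len(pooled) == 0:
        return np.full(len(edges) - 1, np.nan)
    h, _ = np.histogram(pooled, bins=edges, density=True)
    return h


def _binned_mean_cos(local_speeds, cosines, edges):
    idx = np.clip(np.searchsorted(edges, local_speeds, side="right") - 1, 0, len(edges) - 2)
    out_x = np.full(len(edges) - 1, np.nan)
    out_y = np.full(len(edges) - 1, np.nan)
    for b in range(len(edges) - 1):
        m = idx == b
        if m.any():
            out_x[b] = local_speeds[m].mean()
            out_y[b] = cosines[m].mean()
    return out_x, out_y


def speed_class_analysis(
    tracks: TrajectorySet,
    n_classes: int = 5,
    n_boot: int = 1000,
    seed: int | None = None,
    n_angle_bins: int = 10,
    n_speed_bins: int = 8,
) -> SpeedClassTable:
    """Quintile speed classes: turn-angle histograms and conditioned turning.

    Tracks are ranked by mean secant speed and split into ``n_classes``
    equal-count classes (ties broken by stable track order). For each class
    the pooled folded turn-angle histogram and the mean turn cosine vs
    percentile-binned local speed are computed, with bootstrap-over-tracks
    95% bands (conditioned-turning bin edges are frozen at the point
    estimate's percentile edges so resamples are comparable).
    """
    if len(tracks) < n_classes:
        raise ValueError(f"need at least {n_classes} tracks")
    rng = np.random.default_rng(seed)
    per = []
    for tr in tracks:
        steps = secant_velocities(tr)
        turns = turn_angles(steps)
        per.append(
            {
                "track_id": tr.track_id,
                "sample_id": tr.sample_id,
                "mean_speed": float(steps.speeds.mean()),
                "angles": turns.angles,
                "cosines": turns.cosines,
                "local": turns.local_speeds,
            }
        )
    speeds = np.array([p["mean_speed"] for p in per])
    groups = _rank_bins(speeds, n_classes)
    assignments = pd.DataFrame(
        {
            "track_id": [p["track_id"] for p in per],
            "sample_id": [p["sample_id"] for p in per],
            "mean_speed": speeds,
            "speed_class": -1,
        }
    )
    for c, g in enumerate(groups):
        assignments.loc[g, "speed_class"] = c
    angle_edges = np.linspace(0, math.pi, n_angle_bins + 1)
    hist_rows, turning_rows, class_rows = [], [], []
    for c, g in enumerate(groups):
        members = [per[i] for i in g]
        class_rows.append(
            {"speed_class": c, "mean_speed": float(speeds[g].mean()), "n_tracks": len(g)}
        )
        angles_list = [m["angles"] for m in members]
        h = _pooled_angle_hist(angles_list, angle_edges)
        boot_h = np.empty((n_boot, len(h)))
        for b in range(n_boot):
            idx = rng.integers(0, len(members), len(members))
            boot_h[b] = _pooled_angle_hist([members[i]["angles"] for i in idx], angle_edges)
        lo, hi = np.nanpercentile(boot_h, [2.5, 97.5], axis=0)
        centers = 0.5 * (angle_edges[:-1] + angle_edges[1:])
        for j in range(len(h)):
            hist_rows.append(
                {
                    "speed_class": c,
                    "angle_rad": centers[j],
                    "density": h[j],
                    "ci_low": lo[j],
                    "ci_high": hi[j],
                }
            )
        local = np.concatenate([m["local"] for m in members if len(m["local"])])
        cosines = np.concatenate([m["cosines"] for m in members if len(m["cosines"])])
        if len(local) < n_speed_bins:
            continue
        edges = np.unique(np.percentile(local, np.linspace(0, 100, n_speed_bins + 1)))
        edges[-1] = np.inf
        x, y = _binned_mean_cos(local, cosines, edges)
        boot_y = np.empty((n_boot, len(edges) - 1))
        for b in range(n_boot):
            idx = rng.integers(0, len(members), len(members))
            bl = [members[i]["local"] for i in idx if len(members[i]["local"])]
            bc = [members[i]["cosines"] for i in idx if len(members[i]["cosines"])]
            if not bl:
                boot_y[b] = np.nan
                continue
            _, boot_y[b] = _binned_mean_cos(np.concatenate(bl), np.concatenate(bc), edges)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            ylo, yhi = np.nanpercentile(boot_y, [2.5, 97.5], axis=0)
        for j in range(len(x)):
            turning_rows.append(
                {
                    "speed_class": c,
                    "local_speed": x[j],
                    "mean_cos": y[j],
                    "ci_low": ylo[j],
                    "ci_high": yhi[j],
                }
            )
    return SpeedClassTable(
        assignments=assignments,
        class_speeds=pd.DataFrame(class_rows),
        angle_hist=pd.DataFrame(hist_rows),
        conditioned_turning=pd.DataFrame(turning_rows),
        n_classes=n_classes,
    )


# ---------------------------------------------------------------------------
# speed switching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwitchingCurve:
    """Rank correlation of block speeds vs time between blocks.

    ``table`` columns: delta_min, rho (mean Spearman correlation over block
    pairs with that start-time difference), bootstrap 95% CI over tracks, and
    the 95% permutation-null envelope.
    """

    table: pd.DataFrame
    block_minutes: float
    n_tracks: int


def _block_speed_matrix(tracks: TrajectorySet, block_steps: int):
    """(n_tracks, n_blocks) matrix of block-mean secant speeds, NaN-padded."""
    rows = []
    for tr in tracks:
        sp = secant_velocities(tr).speeds
        n_blocks = len(sp) // block_steps
        if n_blocks < 1:
            rows.append(np.empty(0))
            continue
        rows.append(sp[: n_blocks * block_steps].reshape(n_blocks, block_steps).mean(axis=1))
    width = max((len(r) for r in rows), default=0)
    M = np.full((len(rows), width), np.nan)
    for i, r in enumerate(rows):
        M[i, : len(r)] = r
    return M


def _mean_rho_by_delta(M: np.ndarray, min_tracks: int = 10) -> np.ndarray:
    """Average Spearman correlation between block columns, per start-time lag."""
    n_blocks = M.shape[1]
    out = np.full(n_blocks - 1, np.nan)
    for d in range(1, n_blocks):
        rhos = []
        for i in range(n_blocks - d):
            a, b = M[:, i], M[:, i + d]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() >= min_tracks:
                rhos.append(stats.spearmanr(a[ok], b[ok]).statistic)
        if rhos:
            out[d - 1] = float(np.mean(rhos))
    return out


def speed_switching(
    tracks: TrajectorySet,
    block_minutes: float = 19.5,
    n_perm: int = 1000,
    n_boot: int = 1000,
    auto_block: bool = False,
    min_blocks: int = 2,
    seed: int | None = None,
) -> SwitchingCurve:
    """Spearman correlation of per-track block speeds vs block separation.

    Track speeds are averaged on non-overlapping blocks of ``block_minutes``;
    for every pair of blocks the rank correlation across tracks is computed
    and averaged over pairs with equal start-time difference. Confidence
    bands bootstrap over tracks; the null envelope permutes speeds amongst
    tracks independently within each block. With ``auto_block`` the block
    length is chosen from multiples of t_int spanning 5-40 min to maximize
    the adjacent-block correlation.
    """
    t_int_min = tracks.t_int / 60.0
    rng = np.random.default_rng(seed)
    if auto_block:
        lo, hi = int(np.ceil(5 / t_int_min)), int(np.floor(40 / t_int_min))
        best = None
        for bs in range(max(lo, 2), max(hi + 1, 3)):
            M = _block_speed_matrix(tracks, bs)
            M = M[np.sum(~np.isnan(M), axis=1) >= min_blocks]
            if M.shape[1] < 2 or len(M) < 10:
                continue
            rho = _mean_rho_by_delta(M)[0]
            if np.isfinite(rho) and (best is None or rho > best[0]):
                best = (rho, bs)
        if best is None:
            raise ValueError("auto_block: no candidate block length usable")
        block_steps = best[1]
        block_minutes = block_steps * t_int_min
        logger.info("auto_block selected %.2f min blocks", block_minutes)
    else:
        block_steps = int(round(block_minutes * 60.0 / tracks.t_int))
        if block_steps < 1:
            raise ValueError("block shorter than one sampling interval")
    M = _block_speed_matrix(tracks, block_steps)
    usable = np.sum(~np.isnan(M), axis=1) >= min_blocks
    M = M[usable]
    if M.size == 0 or M.shape[1] < 2:
        raise ValueError("no track has at least 2 complete blocks")
    n_blocks = M.shape[1]
    rho = _mean_rho_by_delta(M)
    boot = np.empty((n_boot, n_blocks - 1))
    for b in range(n_boot):
        boot[b] = _mean_rho_by_delta(M[rng.integers(0, len(M), len(M))])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        blo, bhi = np.nanpercentile(boot, [2.5, 97.5], axis=0)
    perm = np.empty((n_perm, n_blocks - 1))
    Mp = M.copy()
    for p in range(n_perm):
        for c in range(n_blocks):
            ok = np.flatnonzero(~np.isnan(M[:, c]))
            Mp[ok, c] = M[rng.permutation(ok), c]
        perm[p] = _mean_rho_by_delta(Mp)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        nlo, nhi = np.nanpercentile(perm, [2.5, 97.5], axis=0)
    table = pd.DataFrame(
        {
            "delta_min": np.arange(1, n_blocks) * block_minutes,
            "rho": rho,
            "ci_low": blo,
            "ci_high": bhi,
            "null_low": nlo,
            "null_high": nhi,
        }
    )
    return SwitchingCurve(table=table, block_minutes=block_minutes, n_tracks=len(M))


# ---------------------------------------------------------------------------
# variance decompositions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceDecomposition:
    """Decomposition of across-track variance in mean turn cosine.

    ``frac_speed``: share explained by the smooth speed-turning relationship;
    ``frac_stochastic``: share attributable to finite-sample noise of each
    track's mean cosine; ``frac_other``: the remainder (clamped at 0).
    """

    frac_speed: float
    frac_stochastic: float
    frac_other: float
    spline: object
    Vs: float
    Vst: float
    Vtot: float


def variance_decomposition_turning(
    summaries: list[MotilitySummary] | pd.DataFrame,
    per_track_cosines: list[np.ndarray],
    smoothing: float | None = None,
    min_turns: int = 3,
) -> VarianceDecomposition:
    """Split the variance of per-track mean turn cosine into speed/noise/other.

    A smoothing spline f is fit to mean cosine vs mean speed across tracks;
    Vs = Var(f(S_m)). The stochastic share is the mean over tracks of the
    squared standard error of the track's mean cosine,
    Vst = mean_m[ Var_j(cos theta_jm) / (k_m - 1) ]. The remainder is "other"
    (spline model error, measurement noise, unmodeled biology).
    """
    df = pd.DataFrame([s.__dict__ for s in summaries]) if not isinstance(
        summaries, pd.DataFrame
    ) else summaries
    if len(df) != len(per_track_cosines):
        raise ValueError("summaries and per_track_cosines must align")
    keep = np.array([len(c) >= min_turns for c in per_track_cosines]) & np.isfinite(
        df["mean_cos"].to_numpy()
    )
    if keep.sum() < 20:
        raise ValueError("need at least 20 tracks with enough turns")
    S = df["mean_speed"].to_numpy()[keep]
    mc = df["mean_cos"].to_numpy()[keep]
    cosines = [c for c, k in zip(per_track_cosines, keep) if k]
    if np.std(S) == 0:
        raise ValueError("degenerate speeds: spline undefined")
    order = np.argsort(S, kind="stable")
    xs, ys = S[order], mc[order]
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    if len(ux) < 4:
        raise ValueError("too few distinct speeds for a spline fit")
    spline = UnivariateSpline(ux, uy, s=smoothing)
    Vs = float(np.var(spline(S), ddof=1))
    Vst = float(np.mean([np.var(c, ddof=0) / (len(c) - 1) for c in cosines]))
    Vtot = float(np.var(mc, ddof=1))
    frac_speed = Vs / Vtot
    frac_stochastic = Vst / Vtot
    frac_other = 1.0 - frac_speed - frac_stochastic
    if frac_other < 0:
        warnings.warn("variance decomposition: components exceed total; clamping 'other' at 0")
        frac_other = 0.0
    return VarianceDecomposition(
        frac_speed=frac_speed,
        frac_stochastic=frac_stochastic,
        frac_other=frac_other,
        spline=spline,
        Vs=Vs,
        Vst=Vst,
        Vtot=Vtot,
    )


def variance_by_sample(summaries: list[MotilitySummary] | pd.DataFrame) -> float:
    """R² of per-track mean speed regressed on sample-identity indicators.

    Equivalent to the between-sample share of the total speed variance.
    """
    from sklearn.linear_model import LinearRegression

    df = pd.DataFrame([s.__dict__ for s in summaries]) if not isinstance(
        summaries, pd.DataFrame
    ) else summaries
    counts = df.groupby("sample_id").size()
    if len(counts) < 2:
        raise ValueError("need at least 2 samples")
    if (counts < 2).any():
        raise ValueError("need at least 2 tracks per sample")
    X = pd.get_dummies(df["sample_id"]).to_numpy(dtype=float)
    y = df["mean_speed"].to_numpy()
    model = LinearRegression().fit(X, y)
    return float(model.score(X, y))
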