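"""Speed-persistence coupling and effective-diffusion scaling.

The coupling analysis bins trajectories into mean-speed deciles, averages the
threshold-crossing persistence time in each bin, and fits the linear law
P = S/alpha + beta. The effective diffusion constant D_eff(tau) = MSD(tau)/4tau
is computed per track at long lags and binned by speed; the uniform-persistence
(D_eff ∝ S²) and speed-persistence-coupling (D_eff ∝ S²(S/alpha + beta))
models are then fit with a single multiplicative constant each.

The threshold-crossing persistence time is a biased estimator of the OU
correlation time P: even with dense noiseless sampling it is proportional to
P with a constant that is a property of the OU process, not 1. The raw fit is
the headline statistic (matching how the binned persistence relationship is
used); :func:`persistence_calibration` measures the proportionality constant
on dense simulations so ground-truth coupling parameters can be recovered.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import _rank_bins
from .io import TrajectorySet
from .kinematics import MotilitySummary, secant_velocities
from . import simulate as sim

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CouplingFit:
    """Decile-binned persistence-vs-speed relationship and linear fit.

    ``alpha`` (µm/min²) is 1/slope and ``beta`` (min) the intercept of the
    weighted fit P = S/alpha + beta to the binned means. ``upt_consistent``
    is set when the slope CI contains zero (no detectable coupling), in which
    case ``alpha`` is reported as inf for a non-positive slope.
    """

    alpha: float
    beta: float
    slope: float
    slope_se: float
    intercept_se: float
    bins: pd.DataFrame  # bin, mean_speed, mean_persistence, ci_low, ci_high, n
    upt_consistent: bool
    n_excluded: int


def persistence_vs_speed(
    summaries: list[MotilitySummary] | pd.DataFrame,
    n_bins: int = 10,
    n_boot: int = 1000,
    seed: int | None = None,
    calibration: tuple[float, float] | None = None,
    weighted: bool = True,
    speed_col: str = "mean_speed",
) -> CouplingFit:
    """Bin tracks into speed deciles and fit the linear speed-persistence law.

    Tracks with undefined persistence time (no turning event) are excluded
    with a logged count. Bin means get bootstrap-over-tracks 95% CIs; the
    line is fit to the binned means, weighted by inverse CI half-width
    variance (``weighted=False`` for the unweighted sensitivity variant).
    ``calibration`` optionally maps the threshold-crossing estimator back to
    the model persistence time before fitting: a ``(c, d)`` pair from
    :func:`persistence_calibration` applies P = (P_tilde - d)/c. The default
    (None) fits the raw measured persistence times, the headline statistic.
    ``speed_col`` selects the speed axis: ``"mean_speed"`` (the headline
    average-speed axis) or ``"rms_speed"`` (the RMS speed, which estimates
    the walk model's S directly and is the right axis when recovering
    ground-truth coupling constants).
    """
    df = pd.DataFrame([s.__dict__ for s in summaries]) if not isinstance(
        summaries, pd.DataFrame
    ) else summaries
    ok = np.isfinite(df["persistence_time"].to_numpy())
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("persistence_vs_speed: excluded %d tracks without a turning event", n_excluded)
    df = df[ok]
    if len(df) < n_bins:
        raise ValueError(f"need at least {n_bins} tracks with defined persistence time")
    S = df[speed_col].to_numpy()
    P = df["persistence_time"].to_numpy()
    if calibration is not None:
        c, d = calibration
        P = (P - d) / c
    if np.ptp(S) == 0:
        raise ValueError("degenerate bins: all mean speeds identical")
    rng = np.random.default_rng(seed)
    groups = _rank_bins(S, n_bins)
    rows = []
    for b, g in enumerate(groups):
        boot = np.array(
            [P[g[rng.integers(0, len(g), len(g))]].mean() for _ in range(n_boot)]
        )
        lo, hi = np.percentile(boot, [2.5, 97.5])
        rows.append(
            {
                "bin": b,
                "mean_speed": float(S[g].mean()),
                "mean_persistence": float(P[g].mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_tracks": len(g),
            }
        )
    bins = pd.DataFrame(rows)
    x = bins["mean_speed"].to_numpy()
    y = bins["mean_persistence"].to_numpy()
    if len(np.unique(x)) < 2:
        raise ValueError("degenerate bins: binned speeds identical")
    if weighted:
        se = (bins["ci_high"] - bins["ci_low"]).to_numpy() / (2 * 1.96)
        se = np.maximum(se, 1e-6)
        w = 1.0 / se**2
    else:
        w = np.ones_like(x)
    A = np.column_stack([x, np.ones_like(x)])
    Aw = A * np.sqrt(w)[:, None]
    yw = y * np.sqrt(w)
    coef, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
    cov = np.linalg.inv(Aw.T @ Aw)
    if not weighted:
        resid = y - A @ coef
        cov = cov * float(resid @ resid) / max(len(x) - 2, 1)
    slope, intercept = float(coef[0]), float(coef[1])
    slope_se = float(np.sqrt(cov[0, 0]))
    intercept_se = float(np.sqrt(cov[1, 1]))
    upt_consistent = bool(slope - 1.96 * slope_se <= 0 <= slope + 1.96 * slope_se)
    alpha = 1.0 / slope if slope > 0 else float("inf")
    return CouplingFit(
        alpha=alpha,
        beta=intercept,
        slope=slope,
        slope_se=slope_se,
        intercept_se=intercept_se,
        bins=bins,
        upt_consistent=upt_consistent,
        n_excluded=n_excluded,
    )


def persistence_calibration(
    P_values=(0.75, 1.0, 1.5, 2.0, 3.0, 4.0),
    S: float = 6.0,
    t_int: float = 6.0,
    duration: float = 90.0,
    n_tracks: int = 100,
    dt: float = 3.0,
    seed: int | None = None,
) -> tuple[float, float]:
    """Affine map (c, d) between the threshold-crossing estimator and P.

    Simulates noiseless OU ensembles over a grid of persistence times at the
    analysis sampling interval ``t_int`` (s) and regresses the mean measured
    persistence time on the true P: P_tilde ~ c P + d. The multiplicative
    part (c) and the finite-sampling offset (d, roughly proportional to
    t_int) are both properties of the estimator at that sampling interval.
    In the noiseless model the turning test is invariant to an overall speed
    rescaling, so one map calibrates all speeds; invert with
    P = (P_tilde - d)/c. The grid should span the persistence range of the
    population under study, and ``t_int``, ``duration`` and the integration
    step ``dt`` should match the tracks being analyzed: the offset scales
    with the sampling interval, the censoring of long persistence episodes
    depends on track length, and the discrete-time integrator itself depends
    on dt, so the map is specific to all three.
    """
    from .kinematics import persistence_time

    rng_seq = np.random.SeedSequence(seed)
    means = []
    for P, child in zip(P_values, rng_seq.spawn(len(P_values))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        pop = sim.PopulationParams(
            n_cells=n_tracks,
            speed_law={"name": "fixed", "value": S},
            coupling=sim.UPT(P0=P),
            duration=duration,
            dt=min(dt, t_int),
            sample_interval=t_int,
            seed=child_seed,
        )
        tracks, _ = sim.simulate_observed(pop)
        pt = np.array([persistence_time(tr) for tr in tracks])
        means.append(np.nanmean(pt))
    c, d = np.polyfit(np.asarray(P_values, dtype=float), np.asarray(means), 1)
    return float(c), float(d)


@dataclass(frozen=True)
class DeffTable:
    """Effective diffusion constants by speed bin and lag.

    ``table`` columns: bin, bin_speed (mean track speed in the bin, µm/min),
    tau_min, deff (µm²/min), bootstrap 95% CI, and the per-lag count of
    qualifying tracks.
    """

    table: pd.DataFrame
    taus: tuple
    bin_frac: float


def deff_table(
    tracks: TrajectorySet,
    taus: list[float] | None = None,
    bin_frac: float = 0.05,
    n_boot: int = 1000,
    seed: int | None = None,
    typical_persistence: float | None = None,
) -> DeffTable:
    """Per-speed-bin effective diffusion constants D_eff(tau) = MSD(tau)/4tau.

    Tracks are divided into speed-quantile bins holding ``bin_frac`` of the
    distribution each; within a bin, per-track D_eff values at each lag are
    averaged over the tracks long enough for that lag (empty bins are
    omitted for that lag). Default ``taus``: five evenly spaced lags in the
    upper half of the available lag range. D_eff has a diffusive meaning only
    for lags well beyond the persistence time; a warning is issued when
    ``typical_persistence`` is given and some lag is below 10x it.
    """
    if len(tracks) == 0:
        raise ValueError("no tracks")
    t_int_min = tracks.t_int / 60.0
    steps = np.array([tr.n_steps for tr in tracks])
    if taus is None:
        top = int(np.percentile(steps, 75))
        ms = np.unique(np.linspace(max(top // 2, 1), top, 5).astype(int))
        taus = [m * t_int_min for m in ms]
    taus = list(taus)
    if typical_persistence is not None and min(taus) < 10 * typical_persistence:
        warnings.warn(
            "some lags are below 10x the typical persistence time; "
            "D_eff is not purely diffusive there"
        )
    mean_speeds = np.empty(len(tracks))
    pos_list = []
    for i, tr in enumerate(tracks):
        mean_speeds[i] = secant_velocities(tr).speeds.mean()
        pos_list.append(tr.positions)
    n_bins = max(int(round(1.0 / bin_frac)), 1)
    groups = _rank_bins(mean_speeds, n_bins)
    rng = np.random.default_rng(seed)
    rows = []
    for tau in taus:
        m = int(round(tau * 60.0 / tracks.t_int))
        if abs(m - tau * 60.0 / tracks.t_int) > 1e-6 or m < 1:
            raise ValueError(f"lag {tau} min is not a multiple of t_int")
        deff = np.full(len(tracks), np.nan)
        for i, pos in enumerate(pos_list):
            if len(pos) > m:
                d = pos[m:] - pos[:-m]
                deff[i] = np.mean(np.einsum("ij,ij->i", d, d)) / (4.0 * tau)
        for b, g in enumerate(groups):
            vals = deff[g]
            ok = np.isfinite(vals)
            if not ok.any():
                continue  # bin empty at this lag
            vals = vals[ok]
            boot = np.array(
                [vals[rng.integers(0, len(vals), len(vals))].mean() for _ in range(n_boot)]
            )
            lo, hi = np.percentile(boot, [2.5, 97.5])
            rows.append(
                {
                    "bin": b,
                    "bin_speed": float(mean_speeds[g].mean()),
                    "tau_min": tau,
                    "deff": float(vals.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "n_tracks": int(ok.sum()),
                }
            )
    return DeffTable(table=pd.DataFrame(rows), taus=tuple(taus), bin_frac=bin_frac)


@dataclass(frozen=True)
class ScalingFit:
    """One-constant fit of a D_eff-vs-speed scaling law.

    ``fold_variation`` is the model-predicted ratio of D_eff between the
    fastest and slowest speed bins present.
    """

    model: str
    constant: float
    rss_log: float
    fold_variation: float


def _shape(model: str, S: np.ndarray, coupling: CouplingFit) -> np.ndarray:
    if model == "UPT":
        return S**2
    if model == "SPC":
        return S**2 * (S / coupling.alpha + coupling.beta)
    raise ValueError(model)


def fit_scaling(deff: DeffTable, coupling: CouplingFit) -> tuple[ScalingFit, ScalingFit]:
    """Fit UPT (D ∝ S²) and SPC (D ∝ S²(S/alpha + beta)) to a D_eff table.

    alpha and beta come from the coupling fit and are NOT refit; the single
    free parameter per model is the multiplicative constant, fit in log space
    weighted by the bootstrap CIs (a vertical offset in log-log that cannot
    change the shape of the curve).
    """
    if not np.isfinite(coupling.alpha) or not np.isfinite(coupling.beta):
        raise ValueError("coupling fit is not finite; cannot anchor the SPC shape")
    tb = deff.table
    tb = tb[np.isfinite(tb["deff"]) & (tb["deff"] > 0) & (tb["ci_low"] > 0)]
    if tb["bin"].nunique() < 4:
        raise ValueError("need at least 4 speed bins with positive D_eff")
    S = tb["bin_speed"].to_numpy()
    logD = np.log(tb["deff"].to_numpy())
    sig = (np.log(tb["ci_high"].to_numpy()) - np.log(tb["ci_low"].to_numpy())) / (2 * 1.96)
    w = 1.0 / np.maximum(sig, 1e-6) ** 2
    Smin, Smax = S.min(), S.max()
    fits = []
    for model in ("UPT", "SPC"):
        shape = np.log(_shape(model, S, coupling))
        logc = float(np.sum(w * (logD - shape)) / np.sum(w))
        resid = logD - logc - shape
        fold = float(
            _shape(model, np.array([Smax]), coupling)[0]
            / _shape(model, np.array([Smin]), coupling)[0]
        )
        fits.append(
            ScalingFit(
                model=model,
                constant=float(np.exp(logc)),
                rss_log=float(resid @ resid),
                fold_variation=fold,
            )
        )
    return fits[0], fits[1]
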