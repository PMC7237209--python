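"""Stochastic simulation of persistent-random-walk cell populations.

The velocity of each walker follows a 2-D Ornstein-Uhlenbeck (OU) process

    dv_i/dt = -v_i / P + (S / sqrt(P)) * xi_i(t),

where ``S`` is the characteristic speed (root-mean-square 2-D speed at
stationarity, µm/min), ``P`` the persistence time (min) and ``xi`` unit white
noise per component. With this normalization the per-component velocity
autocovariance is (S²/2)·exp(-tau/P), the ensemble mean squared displacement
is MSD(tau) = 2 S² P tau (1 + (P/tau)(exp(-tau/P) - 1)), and the long-time
effective diffusion constant is D_eff = MSD/(4 tau) = S² P / 2.

Populations draw a per-cell S from a speed law; the persistence time is
assigned either by speed-persistence coupling (SPC, P = S/alpha + beta, so
faster cells are straighter) or uniformly (UPT, P = P0 for every cell).
An observation model decimates positions to the imaging interval and adds
independent Gaussian mislocation noise per coordinate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SPC:
    """Speed-persistence coupling: P(S) = S/alpha + beta.

    ``alpha`` is an acceleration (µm/min²), ``beta`` a time (min).
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("SPC alpha must be positive")
        if self.beta < 0:
            raise ValueError("SPC beta must be non-negative")

    def persistence(self, S: np.ndarray) -> np.ndarray:
        return np.asarray(S) / self.alpha + self.beta


@dataclass(frozen=True)
class UPT:
    """Uniform persistence time: P = P0 for all cells, regardless of speed."""

    P0: float

    def __post_init__(self):
        if self.P0 <= 0:
            raise ValueError("UPT P0 must be positive")

    def persistence(self, S: np.ndarray) -> np.ndarray:
        return np.full(np.shape(S), self.P0)


@dataclass(frozen=True)
class ModelParams:
    """Single-walker parameters: S (µm/min), P (min), integration and observation.

    ``dt`` is the integration step and ``sample_interval`` the observation
    interval, both in seconds; ``sigma_loc`` is the mislocation-noise standard
    deviation per coordinate in µm.
    """

    S: float
    P: float
    dt: float = 3.0
    sigma_loc: float = 0.0
    sample_interval: float = 45.0
    seed: int | None = None

    def __post_init__(self):
        if self.S < 0:
            raise ValueError("S must be non-negative")
        if self.P <= 0:
            raise ValueError("P must be positive")
        if not (0 < self.dt <= self.sample_interval):
            raise ValueError("need 0 < dt <= sample_interval")
        if self.sigma_loc < 0:
            raise ValueError("sigma_loc must be non-negative")


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of a heterogeneous walker population.

    ``speed_law`` names the per-cell characteristic-speed distribution;
    the default log-normal (median 5 µm/min, log-sd 0.545) spans roughly
    2-12 µm/min between its 5th and 95th percentiles, an order-of-magnitude
    spread. ``switching_rate`` (per minute) redraws a cell's S at exponential
    waiting times (0 = static speeds). ``duration`` is track length in
    minutes; ``dt``/``sample_interval`` in seconds as in :class:`ModelParams`.
    """

    n_cells: int
    speed_law: dict = field(
        default_factory=lambda: {"name": "lognormal", "median": 5.0, "sigma_log": 0.545}
    )
    coupling: SPC | UPT = field(default_factory=lambda: SPC(alpha=4.0, beta=0.5))
    switching_rate: float = 0.0
    duration: float = 180.0
    dt: float = 3.0
    sigma_loc: float = 0.0
    sample_interval: float = 45.0
    sample_id: str = "sim"
    seed: int | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.switching_rate < 0:
            raise ValueError("switching_rate must be non-negative")
        if not (0 < self.dt <= self.sample_interval):
            raise ValueError("need 0 < dt <= sample_interval")


def draw_speeds(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` per-cell characteristic speeds from a named distribution."""
    name = law.get("name", "lognormal")
    if name == "lognormal":
        return rng.lognormal(mean=math.log(law["median"]), sigma=law["sigma_log"], size=n)
    if name == "fixed":
        return np.full(n, float(law["value"]))
    if name == "choice":
        return rng.choice(np.asarray(law["values"], dtype=float), size=n)
    if name == "uniform":
        return rng.uniform(law["low"], law["high"], size=n)
    raise ValueError(f"unknown speed law {name!r}")


def _integrate_ensemble(
    S: np.ndarray,
    P: np.ndarray,
    n_steps: int,
    dt_min: float,
    rng: np.random.Generator,
    switching_rate: float = 0.0,
    speed_law: dict | None = None,
    coupling: SPC | UPT | None = None,
):
    """Euler-Maruyama integration of n independent OU walkers.

    Per component: v <- v (1 - dt/P) + (S/sqrt(P)) sqrt(dt) xi. Velocities are
    initialized from the stationary Gaussian (per-component sd S/sqrt(2)).
    On a switching event the cell's S is redrawn, P updated from the coupling,
    and the velocity rescaled to the new stationary scale.

    Returns positions (n, n_steps+1, 2) in µm and a per-cell list of switch
    events (time_min, new_S).
    """
    S = np.array(S, dtype=float)
    P = np.array(P, dtype=float)
    n = len(S)
    v = rng.standard_normal((n, 2)) * (S / math.sqrt(2.0))[:, None]
    pos = np.zeros((n, n_steps + 1, 2))
    events: list[list[tuple[float, float]]] = [[] for _ in range(n)]
    p_switch = switching_rate * dt_min
    if p_switch >= 1:
        raise ValueError("switching_rate * dt >= 1; reduce dt")
    for t in range(n_steps):
        if p_switch > 0:
            mask = rng.random(n) < p_switch
            if mask.any():
                idx = np.flatnonzero(mask)
                S_new = draw_speeds(speed_law, len(idx), rng)
                with np.errstate(divide="ignore", invalid="ignore"):
                    scale = np.where(S[idx] > 0, S_new / S[idx], 0.0)
                v[idx] *= scale[:, None]
                S[idx] = S_new
                P[idx] = coupling.persistence(S_new)
                for j, i in enumerate(idx):
                    events[i].append((t * dt_min, float(S_new[j])))
        pos[:, t + 1] = pos[:, t] + v * dt_min
        xi = rng.standard_normal((n, 2))
        v = v * (1.0 - dt_min / P)[:, None] + (S / np.sqrt(P))[:, None] * math.sqrt(dt_min) * xi
    return pos, events


def simulate_ou(params: ModelParams, duration: float) -> Trajectory:
    """Integrate a single OU walker for ``duration`` minutes.

    Returns the dense (noise-free) trajectory sampled at the integration step
    ``dt``; apply :func:`apply_observation_model` for decimation and
    mislocation noise.
    """
    if duration * 60.0 < 2 * params.sample_interval:
        raise ValueError("duration must cover at least two observation intervals")
    rng = np.random.default_rng(params.seed)
    dt_min = params.dt / 60.0
    n_steps = int(round(duration / dt_min))
    pos, _ = _integrate_ensemble(
        np.array([params.S]), np.array([params.P]), n_steps, dt_min, rng
    )
    times = np.arange(n_steps + 1) * params.dt
    return Trajectory("ou0", "sim", times, pos[0], params.dt)


def simulate_population(pop: PopulationParams) -> tuple[TrajectorySet, pd.DataFrame]:
    """Simulate a heterogeneous population; return dense tracks + ground truth.

    Each cell draws S from ``speed_law`` and gets P from the coupling
    (P = S/alpha + beta under SPC; P = P0 under UPT). The ground-truth table
    has one row per cell: track_id, S_true, P_true (initial values) and the
    list of switching events. Tracks are dense (interval ``dt``, no noise);
    see :func:`simulate_observed` for the full generative pipeline.
    """
    rng = np.random.default_rng(pop.seed)
    S = draw_speeds(pop.speed_law, pop.n_cells, rng)
    P = np.asarray(pop.coupling.persistence(S), dtype=float)
    dt_min = pop.dt / 60.0
    n_steps = int(round(pop.duration / dt_min))
    pos, events = _integrate_ensemble(
        S, P, n_steps, dt_min, rng, pop.switching_rate, pop.speed_law, pop.coupling
    )
    times = np.arange(n_steps + 1) * pop.dt
    width = max(4, len(str(pop.n_cells)))
    trajectories = [
        Trajectory(f"cell{i:0{width}d}", pop.sample_id, times, pos[i], pop.dt)
        for i in range(pop.n_cells)
    ]
    truth = pd.DataFrame(
        {
            "track_id": [tr.track_id for tr in trajectories],
            "S_true": S,
            "P_true": P,
            "switch_times": [list(ev) for ev in events],
        }
    )
    meta = {"generator": "simulate_population", "params": repr(pop)}
    return TrajectorySet(trajectories, meta), truth


def apply_observation_model(
    tracks: TrajectorySet,
    sigma_loc: float,
    sample_interval: float,
    seed: int | None = None,
) -> TrajectorySet:
    """Decimate to the imaging interval and add Gaussian mislocation noise.

    ``sample_interval`` (s) must be an integer multiple of each track's
    current interval. Independent N(0, sigma_loc²) noise is added to each
    coordinate of each retained timepoint.
    """
    rng = np.random.default_rng(seed)
    out = []
    for tr in tracks:
        ratio = sample_interval / tr.t_int
        factor = int(round(ratio))
        if abs(ratio - factor) > 1e-9 or factor < 1:
            raise ValueError(
                f"sample_interval {sample_interval} is not a multiple of t_int {tr.t_int}"
            )
        times = tr.times[::factor]
        pos = tr.positions[::factor].copy()
        if sigma_loc > 0:
            pos += rng.normal(0.0, sigma_loc, size=pos.shape)
        out.append(replace(tr, times=times, positions=pos, t_int=sample_interval))
    meta = dict(tracks.metadata)
    meta["observation"] = {"sigma_loc": sigma_loc, "sample_interval": sample_interval}
    return TrajectorySet(out, meta)


def simulate_observed(pop: PopulationParams) -> tuple[TrajectorySet, pd.DataFrame]:
    """Population simulation followed by the observation model (one call).

    The observation seed is derived from the population seed so a single seed
    fixes the entire generative process.
    """
    dense, truth = simulate_population(pop)
    obs_seed = None
    if pop.seed is not None:
        obs_seed = int(np.random.SeedSequence(pop.seed).spawn(1)[0].generate_state(1)[0] % (2**31))
    observed = apply_observation_model(dense, pop.sigma_loc, pop.sample_interval, seed=obs_seed)
    return observed, truth


def theoretical_msd(tau: np.ndarray, S: float, P: float, sigma_loc: float = 0.0) -> np.ndarray:
    """Closed-form ensemble MSD of the OU walker (µm²; tau in minutes).

    MSD(tau) = 2 S² P tau (1 + (P/tau)(exp(-tau/P) - 1)) + 4 sigma_loc².
    The offset is the mislocation-noise contribution to the squared
    displacement of two independently-noisy positions (2 coords x 2 points).
    """
    tau = np.asarray(tau, dtype=float)
    return 2.0 * S**2 * P * tau * (1.0 + (P / tau) * np.expm1(-tau / P)) + 4.0 * sigma_loc**2
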