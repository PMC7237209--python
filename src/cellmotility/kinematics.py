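"""Per-trajectory kinematic quantities.

Everything downstream is built from secant approximations: the velocity over a
sampling interval is the displacement between consecutive sampled positions
divided by the interval. Turn angles are the angles between consecutive secant
steps, folded to [0, pi]; the persistence time is the mean time until the
trajectory turns by more than a threshold angle relative to a base step.
Speeds are reported in µm/min, angles in radians.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import Trajectory

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepSeries:
    """Secant velocities of one trajectory (µm/min), one per step."""

    velocities: np.ndarray  # (n_steps, 2)
    speeds: np.ndarray  # (n_steps,)
    t_int: float  # seconds
    step_times: np.ndarray  # step midpoints, seconds

    def __len__(self) -> int:
        return len(self.speeds)


@dataclass(frozen=True)
class TurnSeries:
    """Turn angles between consecutive steps of one trajectory.

    Turns adjacent to a degenerate (zero-length, or below ``min_step``) step
    are excluded because their direction is undefined; ``n_excluded`` counts
    them. ``local_speeds`` is the mean of the two step speeds around each turn.
    """

    angles: np.ndarray  # radians in [0, pi]
    cosines: np.ndarray
    local_speeds: np.ndarray  # µm/min
    n_excluded: int

    def __len__(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class MotilitySummary:
    """Coordinates of one trajectory in the behavioral space.

    ``mean_speed`` (µm/min), ``rms_speed`` (root-mean-square secant speed,
    the natural estimator of the walk model's characteristic speed S),
    ``mean_cos`` (mean turn-angle cosine), ``local_corr`` (Pearson
    correlation of local speed vs turn angle along the track) and
    ``persistence_time`` (min; NaN when no turning event occurs).
    """

    track_id: str
    sample_id: str
    mean_speed: float
    rms_speed: float
    mean_cos: float
    local_corr: float
    persistence_time: float
    n_steps: int
    n_turns: int


def secant_velocities(traj: Trajectory) -> StepSeries:
    """Displacement per sampling interval, converted to µm/min.

    Assumes a gap-free (preprocessed) trajectory; with gaps present the secant
    over a gap would span several intervals, so a validation error is raised.
    """
    if traj.has_gaps():
        raise ValueError(
            f"track {traj.track_id!r} has gaps; preprocess() before computing velocities"
        )
    disp = np.diff(traj.positions, axis=0)
    vel = disp / traj.t_int * 60.0  # µm/s -> µm/min
    speeds = np.hypot(vel[:, 0], vel[:, 1])
    return StepSeries(
        velocities=vel,
        speeds=speeds,
        t_int=traj.t_int,
        step_times=0.5 * (traj.times[:-1] + traj.times[1:]),
    )


def turn_angles(steps: StepSeries, min_step: float = 0.0) -> TurnSeries:
    """Angles between consecutive secant steps, folded to [0, pi].

    ``min_step`` is a step-length threshold in µm; turns where either adjacent
    step length is <= ``min_step`` are excluded (with ``min_step=0`` this
    drops only exactly zero-length steps, whose direction is undefined).
    """
    v = steps.velocities
    if len(v) < 2:
        return TurnSeries(np.empty(0), np.empty(0), np.empty(0), 0)
    a, b = v[:-1], v[1:]
    step_len = steps.speeds * steps.t_int / 60.0  # µm
    ok = (step_len[:-1] > min_step) & (step_len[1:] > min_step)
    n_excluded = int(np.sum(~ok))
    if n_excluded:
        logger.debug("turn_angles: excluded %d degenerate turns", n_excluded)
    a, b = a[ok], b[ok]
    dot = np.einsum("ij,ij->i", a, b)
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    angles = np.arctan2(np.abs(cross), dot)  # folded to [0, pi] by |cross|
    cosines = np.cos(angles)
    local = 0.5 * (steps.speeds[:-1] + steps.speeds[1:])[ok]
    return TurnSeries(angles=angles, cosines=cosines, local_speeds=local, n_excluded=n_excluded)


def persistence_time(
    traj: Trajectory, threshold: float = math.pi / 2, max_lag: int | None = None
) -> float:
    """Mean time (minutes) before the track turns by more than ``threshold``.

    For each base step ``s`` with displacement vector x(s), find the first
    later step ``m`` whose displacement makes an angle greater than
    ``threshold`` with x(s) (for the default pi/2 this is the dot-product test
    x(s)·x(m) < 0); the elapsed time is (m - s)·t_int. The persistence time is
    the average over all base steps for which such an ``m`` exists within the
    track (later base points are censored). Returns NaN when no base step
    terminates (e.g. a perfectly straight track).
    """
    disp = np.diff(traj.positions, axis=0)
    n = len(disp)
    if n < 2:
        return math.nan
    use_dot = abs(threshold - math.pi / 2) < 1e-12
    cos_thr = math.cos(threshold)
    norms = np.hypot(disp[:, 0], disp[:, 1])
    first = np.full(n, -1, dtype=int)  # terminating lag per base step
    open_mask = np.ones(n, dtype=bool)
    open_mask[-1] = False  # last step has no later step
    lag_cap = n - 1 if max_lag is None else min(max_lag, n - 1)
    for d in range(1, lag_cap + 1):
        base = np.flatnonzero(open_mask[: n - d])
        if len(base) == 0:
            # bases beyond n - d have no later step to terminate against
            break
        a = disp[base]
        b = disp[base + d]
        dot = np.einsum("ij,ij->i", a, b)
        if use_dot:
            turned = dot < 0
        else:
            denom = norms[base] * norms[base + d]
            with np.errstate(invalid="ignore", divide="ignore"):
                cosang = np.where(denom > 0, dot / denom, 1.0)
            turned = cosang < cos_thr
        hit = base[turned]
        first[hit] = d
        open_mask[hit] = False
    lags = first[first > 0]
    if len(lags) == 0:
        return math.nan
    return float(np.mean(lags) * traj.t_int / 60.0)


def bout_lengths(traj: Trajectory) -> np.ndarray:
    """Normalized lengths of runs of same-sign x-displacement.

    Consecutive x-displacements with the same sign are summed into a bout;
    zero displacements do not terminate a bout (the sign carries over, and
    leading zeros join the first bout). Each bout's absolute length is divided
    by the trajectory's mean bout length, so the returned values average to 1.
    Returns an empty array for a track with no x motion.
    """
    dx = np.diff(traj.positions[:, 0])
    sign = np.sign(dx)
    nz = np.flatnonzero(sign != 0)
    if len(nz) == 0:
        return np.empty(0)
    # carry the previous non-zero sign over zeros; back-fill leading zeros
    filled = sign.copy()
    last = sign[nz[0]]
    for i in range(len(filled)):
        if filled[i] == 0:
            filled[i] = last
        else:
            last = filled[i]
    breaks = np.flatnonzero(np.diff(filled) != 0)
    bouts = np.abs(np.add.reduceat(dx, np.concatenate(([0], breaks + 1))))
    return bouts / bouts.mean()


def summarize(traj: Trajectory, min_turns_for_corr: int = 3) -> MotilitySummary:
    """All behavioral-space coordinates of one preprocessed trajectory."""
    steps = secant_velocities(traj)
    turns = turn_angles(steps)
    mean_speed = float(steps.speeds.mean())
    mean_cos = float(turns.cosines.mean()) if len(turns) else math.nan
    local_corr = math.nan
    if len(turns) >= min_turns_for_corr:
        if np.std(turns.local_speeds) > 1e-12 and np.std(turns.angles) > 1e-12:
            local_corr = float(stats.pearsonr(turns.local_speeds, turns.angles)[0])
    return MotilitySummary(
        track_id=traj.track_id,
        sample_id=traj.sample_id,
        mean_speed=mean_speed,
        rms_speed=float(np.sqrt(np.mean(steps.speeds**2))),
        mean_cos=mean_cos,
        local_corr=local_corr,
        persistence_time=persistence_time(traj),
        n_steps=len(steps),
        n_turns=len(turns),
    )


def summarize_set(tracks) -> "pd.DataFrame":
    """Per-track :func:`summarize` as a DataFrame (one row per trajectory)."""
    import pandas as pd

    rows = [summarize(tr).__dict__ for tr in tracks]
    return pd.DataFrame(rows)
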