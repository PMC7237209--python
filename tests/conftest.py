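"""Shared fixtures: small deterministic track sets and simulated ensembles."""

import numpy as np
import pytest

from cellmotility.io import Trajectory
from cellmotility import simulate as sim


def make_track(positions, t_int=45.0, track_id="t0", sample_id="s0", times=None):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions)) * t_int
    return Trajectory(track_id, sample_id, np.asarray(times, dtype=float), positions, t_int)


@pytest.fixture
def straight_track():
    """Constant-velocity track: 5 µm/45 s = 6.667 µm/min along +x, 40 steps."""
    x = np.arange(41) * 5.0
    return make_track(np.column_stack([x, np.zeros_like(x)]), track_id="straight")


@pytest.fixture
def random_walk_track():
    rng = np.random.default_rng(42)
    pos = np.cumsum(rng.normal(0, 2.0, size=(60, 2)), axis=0)
    return make_track(pos, track_id="rw")


@pytest.fixture(scope="session")
def ou_ensemble():
    """400 homogeneous OU walkers (S=6 µm/min, P=2 min), 60 min at 45 s."""
    pop = sim.PopulationParams(
        n_cells=400,
        speed_law={"name": "fixed", "value": 6.0},
        coupling=sim.UPT(P0=2.0),
        duration=60.0,
        dt=9.0,
        sample_interval=45.0,
        seed=1234,
    )
    tracks, truth = sim.simulate_observed(pop)
    return tracks, truth


@pytest.fixture(scope="session")
def spc_population():
    """Default heterogeneous SPC population (alpha=4, beta=0.5), 150 min."""
    pop = sim.PopulationParams(
        n_cells=200, duration=150.0, dt=9.0, sample_interval=45.0, seed=91
    )
    tracks, truth = sim.simulate_observed(pop)
    return tracks, truth
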