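"""Shared fixtures: small simulated sessions with planted ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from hippogeom import synth
from hippogeom.grid import Grid


@pytest.fixture(scope="session")
def task_config() -> synth.TaskConfig:
    return synth.TaskConfig()


@pytest.fixture(scope="session")
def pursuit_session(task_config):
    """Small pursuit session with gaze attached (no spikes)."""
    s = synth.simulate_session(task_config, n_trials=40, seed=11)
    return synth.attach_gaze(s, synth.simulate_gaze(s, seed=12))


@pytest.fixture(scope="session")
def rw_session():
    """300 s random-walk session: variables are mutually independent."""
    return synth.random_walk_session(18_000, ("self", "chosen_prey"), seed=21)


def planted_session(
    base,
    n_neurons: int = 40,
    angle: float = 60.0,
    map_gain_rms: float = 0.5,
    axis_gain: float = 0.0,
    axis_relation: str = "orthogonal",
    seed: int = 0,
):
    """Attach spikes from a planted two-variable population to a session.

    ``map_gain_rms`` is the target per-bin log-rate RMS; the raw gain is
    rescaled by sqrt(N/d) to keep per-neuron tuning depth independent of
    population size.
    """
    d = 4
    spec = synth.GeometrySpec(
        variables=("self", "chosen_prey"),
        latent_dim=d,
        angles_deg={"chosen_prey": angle},
        axis_relation={"chosen_prey": axis_relation},
        axis_gain=axis_gain,
        map_gain=map_gain_rms * np.sqrt(n_neurons / d),
    )
    pop = synth.plant_population(spec, n_neurons=n_neurons, seed=seed)
    out = synth.Session(
        trajectories=base.trajectories,
        trials=base.trials,
        spikes=synth.simulate_spikes(base, pop, seed=seed + 1),
        frame_dt=base.frame_dt,
        field_size=base.field_size,
        meta=dict(base.meta),
    )
    return out, pop


@pytest.fixture(scope="session")
def planted_rw(rw_session):
    """Random-walk session + spikes from a 60-degree planted population."""
    return planted_session(rw_session, n_neurons=40, angle=60.0, seed=31)


@pytest.fixture(scope="session")
def grid() -> Grid:
    return Grid()
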