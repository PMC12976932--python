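"""Self-contained calibration experiments on fully synthetic sessions.

Each function simulates its own data from a root seed, runs one pipeline
component under its standard settings, and returns the headline number:

* :func:`null_ccgp_calibration` — mean CCGP over label-shuffled designs
  (should sit at chance, 0.5);
* :func:`spaef_self_similarity` — SPAEF between a planted rate map and an
  identical copy (exactly 1);
* :func:`alignment_self_index` — alignment index of a population matrix
  with itself (exactly 1);
* :func:`glm_type_i_rate` — fraction of constant-rate Poisson neurons the
  forward-selection GLM declares spatially tuned (should respect the
  nominal 5% level).
"""

from __future__ import annotations

import numpy as np

from . import ccgp as ccgp_mod
from . import glm as glm_mod
from . import maps as maps_mod
from . import similarity as sim_mod
from . import subspaces as sub_mod
from . import synth
from .grid import Grid


def _planted_pursuit_session(
    n_trials: int, n_neurons: int, seed: int, predator: bool = True
) -> synth.Session:
    """Pursuit session + spikes from a planted two-variable population."""
    ss = np.random.SeedSequence(seed)
    s_beh, s_gaze, s_pop, s_spk = (s.generate_state(1)[0] % 2**31
                                   for s in ss.spawn(4))
    cfg = synth.TaskConfig(predator_enabled=predator)
    session = synth.simulate_session(cfg, n_trials=n_trials, seed=int(s_beh))
    session = synth.attach_gaze(
        session, synth.simulate_gaze(session, seed=int(s_gaze))
    )
    d = 4
    spec = synth.GeometrySpec(
        variables=("self", "chosen_prey"),
        latent_dim=d,
        angles_deg={"chosen_prey": 60.0},
        axis_relation={"chosen_prey": "shared"},
        axis_gain=0.5 * np.sqrt(n_neurons),
        map_gain=0.35 * np.sqrt(n_neurons / d),
    )
    pop = synth.plant_population(spec, n_neurons=n_neurons, seed=int(s_pop))
    session.spikes = synth.simulate_spikes(session, pop, seed=int(s_spk))
    return session


def null_ccgp_calibration(
    seed: int = 0,
    n_neurons: int = 100,
    n_trials: int = 100,
    n_shuffles: int = 100,
    n_reps: int = 20,
) -> tuple[float, int]:
    """Mean cross-context accuracy under within-context label permutation.

    Returns (null mean accuracy, number of design rows used).  A calibrated
    procedure sits at chance (0.5) regardless of the planted geometry.
    """
    session = _planted_pursuit_session(n_trials, n_neurons, seed)
    chunks = ccgp_mod.chunk_session(session, 40.0, ("self", "chosen_prey"))
    d_self = ccgp_mod.build_ccgp_design(chunks, "self")
    d_prey = ccgp_mod.build_ccgp_design(chunks, "chosen_prey")
    res = ccgp_mod.ccgp_null(
        d_self, d_prey, n_shuffles=n_shuffles, n_reps=n_reps,
        seed=seed + 1,
    )
    return float(res.null.mean()), len(d_self.X)


def spaef_self_similarity(seed: int = 0) -> float:
    """SPAEF between a planted tuned neuron's rate map and its copy."""
    base = synth.random_walk_session(9_000, ("self", "chosen_prey"),
                                     seed=seed)
    session = synth.Session(
        trajectories=base.trajectories,
        trials=base.trials,
        frame_dt=base.frame_dt,
        field_size=base.field_size,
    )
    pop = synth.untuned_population(1, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    pop.weight_maps["self"][0] = rng.normal(0.0, 0.6, 36)
    session.spikes = synth.simulate_spikes(session, pop, seed=seed + 3)
    grid = Grid(*session.field_size)
    bins = maps_mod.bin_position(session.trajectories["self"], grid, session)
    rm = maps_mod.compute_rate_map(session.spikes, bins, neuron_id=0)
    return sim_mod.spaef(rm.vector, rm.vector.copy()).spaef


def alignment_self_index(seed: int = 0, n_neurons: int = 60) -> float:
    """Alignment index of a simulated population matrix with itself."""
    base = synth.random_walk_session(12_000, ("self", "chosen_prey"),
                                     seed=seed)
    d = 4
    spec = synth.GeometrySpec(
        variables=("self", "chosen_prey"),
        latent_dim=d,
        angles_deg={"chosen_prey": 60.0},
        map_gain=0.4 * np.sqrt(n_neurons / d),
        noise_sd=0.05,
    )
    pop = synth.plant_population(spec, n_neurons=n_neurons, seed=seed + 1)
    session = synth.Session(
        trajectories=base.trajectories,
        trials=base.trials,
        spikes=synth.simulate_spikes(base, pop, seed=seed + 2),
        frame_dt=base.frame_dt,
        field_size=base.field_size,
    )
    mats = maps_mod.population_matrices(session, ["self", "chosen_prey"])
    return sub_mod.alignment_index_value(mats["self"], mats["self"], k=10)


def glm_type_i_rate(
    seed: int = 0,
    n_neurons: int = 100,
    n_trials: int = 200,
    min_frames: int = 20_000,
    alpha: float = 0.05,
    candidates: tuple[str, ...] = ("self", "chosen_prey", "unchosen_prey",
                                   "gaze"),
) -> tuple[float, int, int]:
    """Fraction of constant-rate neurons declared tuned by forward selection.

    Simulates pursuit behavior (no predator, so every variable is defined on
    most frames), attaches spikes from spatially untuned Poisson neurons and
    runs the full forward-selection procedure per neuron.  Returns
    (fraction declared tuned, n_neurons, analyzable frames).
    """
    ss = np.random.SeedSequence(seed)
    s_beh, s_gaze, s_pop, s_spk = (s.generate_state(1)[0] % 2**31
                                   for s in ss.spawn(4))
    cfg = synth.TaskConfig(predator_enabled=False)
    session = synth.simulate_session(cfg, n_trials=n_trials, seed=int(s_beh))
    session = synth.attach_gaze(
        session, synth.simulate_gaze(session, seed=int(s_gaze))
    )
    pop = synth.untuned_population(
        n_neurons, variables=("self", "chosen_prey"), seed=int(s_pop)
    )
    session.spikes = synth.simulate_spikes(session, pop, seed=int(s_spk))

    grid = Grid(*session.field_size)
    bins = {
        v: maps_mod.bin_position(session.trajectories[v], grid, session)
        for v in candidates
    }
    base = glm_mod.build_design_matrix([bins[v] for v in candidates])
    if base.n_frames < min_frames:
        raise RuntimeError(
            f"only {base.n_frames} analyzable frames; increase n_trials"
        )
    declared = 0
    for i in range(n_neurons):
        model = glm_mod.select_model(
            bins, session.spikes.counts[:, i], neuron_id=i,
            candidates=candidates, alpha=alpha, dt=session.frame_dt,
        )
        declared += int(model.tuned)
    return declared / n_neurons, n_neurons, base.n_frames
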