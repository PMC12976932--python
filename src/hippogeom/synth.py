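"""Synthetic prey-pursuit behavior and Poisson spike trains with known ground truth.

The simulator emulates a joystick pursuit game on an 1800 x 1000 px screen at
60 Hz: a self-controlled avatar chases one or two prey while, on half of the
trials, a predator chases the avatar.  Prey move by minimum-cost selection
over 15 candidate positions (center bias + sigmoidal avatar repulsion); the
predator greedily minimizes its distance to the avatar; the built-in avatar
policy is noisy proportional pursuit of a chosen prey.  Trials end at capture
(spatial tangency) or after a 20 s timeout.

Neural data are generated from a log-linear Poisson model whose per-variable
6x6 weight maps are *planted* with controllable population geometry
(principal angles between variable subspaces, a linear map between latent
coordinates, shared/inverted/orthogonal left-right decoding axes), so every
downstream analysis can be checked against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import Session, SpikeMatrix, Trajectory, make_trials_frame
from .grid import Grid


class GenerationError(RuntimeError):
    """Raised when a random construction fails after bounded retries."""


class ConfigurationError(ValueError):
    """Raised for invalid simulator configuration."""


# ---------------------------------------------------------------------------
# Task configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreySpec:
    """One prey type: top speed (px/frame) and its capture reward (points)."""

    max_speed: float = 18.0
    reward: int = 3


@dataclass(frozen=True)
class TaskConfig:
    field_width: float = 1800.0
    field_height: float = 1000.0
    frame_dt: float = 1.0 / 60.0
    avatar_max_speed: float = 23.0
    prey: tuple[PreySpec, ...] = (PreySpec(16.0, 2), PreySpec(19.0, 4))
    predator_enabled: bool = True
    predator_speed: float = 16.0
    predator_trial_prob: float = 0.5
    trial_timeout: float = 20.0
    min_initial_separation: float = 400.0
    avatar_radius: float = 7.5  # 15 px diameter circle
    prey_half_side: float = 15.0  # 30 px square
    capture_rule: str = "center_distance"  # or "tangency"
    capture_threshold: float = 22.5  # avatar_radius + prey_half_side
    center_bias_strength: float = 0.3
    repulsion_midpoint: float = 200.0  # px
    repulsion_slope: float = 0.02  # 1/px
    repulsion_cutoff: float = 545.0  # px, where sigmoid cost < 1e-3
    n_prey_candidates: int = 15
    heading_noise_kappa: float = 2.0  # avatar policy von Mises concentration
    inter_trial_gap_frames: int = 30

    def __post_init__(self) -> None:
        if self.frame_dt <= 0 or self.trial_timeout <= 0:
            raise ConfigurationError("frame_dt and trial_timeout must be positive")
        if self.avatar_max_speed <= 0 or any(p.max_speed <= 0 for p in self.prey):
            raise ConfigurationError("all speeds must be positive")
        if not 1 <= len(self.prey) <= 2:
            raise ConfigurationError("n_prey must be 1 or 2")
        if self.min_initial_separation >= min(self.field_width, self.field_height):
            raise ConfigurationError(
                "min_initial_separation must be smaller than the field"
            )
        if self.capture_rule not in ("center_distance", "tangency"):
            raise ConfigurationError(f"unknown capture rule {self.capture_rule!r}")

    @property
    def n_prey(self) -> int:
        return len(self.prey)

    @property
    def timeout_frames(self) -> int:
        return int(round(self.trial_timeout / self.frame_dt))

    @property
    def center(self) -> np.ndarray:
        return np.array([self.field_width / 2.0, self.field_height / 2.0])


# ---------------------------------------------------------------------------
# Movement rules
# ---------------------------------------------------------------------------


def _clip_to_field(pos: np.ndarray, cfg: TaskConfig) -> np.ndarray:
    return np.clip(pos, [0.0, 0.0], [cfg.field_width, cfg.field_height])


def _repulsion_cost(dist: float | np.ndarray, cfg: TaskConfig) -> np.ndarray:
    """Sigmoidal cost of proximity to the avatar; zero beyond the cutoff."""
    dist = np.asarray(dist, dtype=float)
    cost = 1.0 / (1.0 + np.exp(cfg.repulsion_slope * (dist - cfg.repulsion_midpoint)))
    return np.where(dist > cfg.repulsion_cutoff, 0.0, cost)


def _center_cost(pos: np.ndarray, cfg: TaskConfig) -> np.ndarray:
    half_diag = 0.5 * math.hypot(cfg.field_width, cfg.field_height)
    d = np.linalg.norm(pos - cfg.center, axis=-1)
    return cfg.center_bias_strength * (d / half_diag) ** 2


def prey_step(
    prey_pos: np.ndarray, avatar_pos: np.ndarray, speed: float, cfg: TaskConfig
) -> np.ndarray:
    """Minimum-cost move over candidates equally spaced on a circle.

    Candidates falling off screen are skipped in ascending cost order; if all
    candidates are off screen (impossible for sane speeds) the prey stays put.
    """
    k = cfg.n_prey_candidates
    ang = 2.0 * np.pi * np.arange(k) / k
    cand = prey_pos + speed * np.column_stack([np.cos(ang), np.sin(ang)])
    cost = _center_cost(cand, cfg) + _repulsion_cost(
        np.linalg.norm(cand - avatar_pos, axis=1), cfg
    )
    on_screen = (
        (cand[:, 0] >= 0)
        & (cand[:, 0] <= cfg.field_width)
        & (cand[:, 1] >= 0)
        & (cand[:, 1] <= cfg.field_height)
    )
    order = np.argsort(cost, kind="stable")
    for i in order:
        if on_screen[i]:
            return cand[i]
    return prey_pos.copy()


def predator_step(
    predator_pos: np.ndarray, avatar_pos: np.ndarray, cfg: TaskConfig
) -> np.ndarray:
    """Greedy max-speed move toward the avatar (single-rule pursuer)."""
    delta = avatar_pos - predator_pos
    dist = float(np.linalg.norm(delta))
    if dist <= cfg.predator_speed:
        return avatar_pos.copy()
    return _clip_to_field(predator_pos + delta * (cfg.predator_speed / dist), cfg)


def _captured(avatar: np.ndarray, prey: np.ndarray, cfg: TaskConfig) -> bool:
    if cfg.capture_rule == "center_distance":
        return float(np.linalg.norm(avatar - prey)) <= cfg.capture_threshold
    # exact circle-square tangency: distance from circle center to the square
    d = np.maximum(np.abs(avatar - prey) - cfg.prey_half_side, 0.0)
    return float(np.linalg.norm(d)) <= cfg.avatar_radius


AVATAR_POLICIES = ("pursuit", "frozen")


def _avatar_step(
    policy: str,
    avatar: np.ndarray,
    target: np.ndarray | None,
    cfg: TaskConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    if policy == "frozen":
        return avatar.copy()
    # noisy proportional pursuit: head toward the chosen prey with von Mises
    # heading noise, speed capped at the joystick limit
    delta = target - avatar
    dist = float(np.linalg.norm(delta))
    if dist < 1e-9:
        return avatar.copy()
    heading = math.atan2(delta[1], delta[0])
    heading += rng.vonmises(0.0, cfg.heading_noise_kappa)
    speed = min(cfg.avatar_max_speed, dist)
    step = speed * np.array([math.cos(heading), math.sin(heading)])
    return _clip_to_field(avatar + step, cfg)


# ---------------------------------------------------------------------------
# Trial / session simulation
# ---------------------------------------------------------------------------

_SPAWN_OFFSET = 450.0  # px from center, cardinal spawn points


def _initial_positions(
    cfg: TaskConfig, rng: np.random.Generator, max_tries: int = 100
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Avatar at center; prey on distinct cardinal points >= 400 px away."""
    avatar = cfg.center.copy()
    offsets = np.array(
        [
            [_SPAWN_OFFSET, 0.0],
            [-_SPAWN_OFFSET, 0.0],
            [0.0, _SPAWN_OFFSET],
            [0.0, -_SPAWN_OFFSET],
        ]
    )
    for _ in range(max_tries):
        idx = rng.permutation(4)[: cfg.n_prey]
        prey = [_clip_to_field(cfg.center + offsets[i], cfg) for i in idx]
        if all(
            np.linalg.norm(p - avatar) >= cfg.min_initial_separation for p in prey
        ):
            return avatar, prey
    raise GenerationError("could not place prey at the required separation")


def simulate_trial(
    config: TaskConfig,
    policy: str = "pursuit",
    seed: int | np.random.Generator = 0,
    trial_id: int = 0,
    start_frame: int = 0,
    force_predator: bool | None = None,
) -> tuple[dict[str, Trajectory], dict]:
    """Simulate one trial; returns per-variable trajectories and a trial record.

    Trajectory keys are ``self``, ``prey_0`` [, ``prey_1``] and ``predator``
    (invalid throughout on predator-free trials).  Chosen/unchosen labels are
    assigned by :func:`simulate_session` once the outcome is known.
    """
    if policy not in AVATAR_POLICIES:
        raise ConfigurationError(f"unknown avatar policy {policy!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    avatar, prey_pos = _initial_positions(config, rng)
    has_predator = (
        force_predator
        if force_predator is not None
        else config.predator_enabled and rng.random() < config.predator_trial_prob
    )
    predator = None
    if has_predator:
        # spawn behind the avatar relative to the first prey, near a corner
        corners = np.array(
            [
                [40.0, 40.0],
                [config.field_width - 40.0, 40.0],
                [40.0, config.field_height - 40.0],
                [config.field_width - 40.0, config.field_height - 40.0],
            ]
        )
        predator = corners[rng.integers(4)].copy()

    # chosen target for the pursuit policy: nearest prey at trial start
    target_idx = int(
        np.argmin([np.linalg.norm(p - avatar) for p in prey_pos])
    )

    max_frames = config.timeout_frames
    n_prey = config.n_prey
    pos_self = np.empty((max_frames, 2))
    pos_prey = [np.empty((max_frames, 2)) for _ in range(n_prey)]
    pos_pred = np.full((max_frames, 2), np.nan)

    outcome = "timeout"
    captured_prey: int | None = None
    t_end = max_frames
    for t in range(max_frames):
        pos_self[t] = avatar
        for j in range(n_prey):
            pos_prey[j][t] = prey_pos[j]
        if predator is not None:
            pos_pred[t] = predator

        # capture checks on current positions
        for j in range(n_prey):
            if _captured(avatar, prey_pos[j], config):
                outcome, captured_prey = "captured", j
                break
        if outcome == "captured":
            t_end = t + 1
            break
        if predator is not None and float(
            np.linalg.norm(avatar - predator)
        ) <= config.capture_threshold:
            outcome = "caught_by_predator"
            t_end = t + 1
            break

        # synchronous update
        new_avatar = _avatar_step(policy, avatar, prey_pos[target_idx], config, rng)
        prey_pos = [
            prey_step(prey_pos[j], avatar, config.prey[j].max_speed, config)
            for j in range(n_prey)
        ]
        if predator is not None:
            predator = predator_step(predator, avatar, config)
        avatar = new_avatar

    frames = np.arange(start_frame, start_frame + t_end)
    t_s = frames * config.frame_dt
    valid = np.ones(t_end, dtype=bool)

    def _traj(name: str, arr: np.ndarray, ok: np.ndarray) -> Trajectory:
        return Trajectory(name, frames, t_s, arr[:t_end, 0], arr[:t_end, 1], ok)

    trajs = {"self": _traj("self", pos_self, valid)}
    for j in range(n_prey):
        trajs[f"prey_{j}"] = _traj(f"prey_{j}", pos_prey[j], valid)
    pred_valid = valid if predator is not None else np.zeros(t_end, dtype=bool)
    trajs["predator"] = _traj("predator", pos_pred, pred_valid)

    reward = config.prey[captured_prey].reward if captured_prey is not None else 0
    if outcome == "caught_by_predator":
        reward = -3
    record = {
        "trial_id": trial_id,
        "start_frame": start_frame,
        "end_frame": start_frame + t_end,
        "outcome": outcome,
        # pursuit target stands in for the chosen prey on non-captured trials
        "chosen_prey_id": captured_prey if captured_prey is not None else target_idx,
        "reward": reward,
    }
    return trajs, record


def simulate_session(
    config: TaskConfig = TaskConfig(),
    n_trials: int = 100,
    seed: int = 0,
    policy: str = "pursuit",
) -> Session:
    """Simulate ``n_trials`` trials concatenated with invalid inter-trial gaps.

    The returned session exposes ``self``, ``chosen_prey``, ``unchosen_prey``
    (invalid on one-prey sessions) and ``predator`` trajectories.  Gaze is
    added separately by :func:`simulate_gaze`.
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    trial_seeds = ss.spawn(n_trials)

    gap = config.inter_trial_gap_frames
    pieces: list[dict[str, Trajectory]] = []
    records: list[dict] = []
    frame = 0
    for i in range(n_trials):
        rng = np.random.default_rng(trial_seeds[i])
        trajs, rec = simulate_trial(
            config, policy=policy, seed=rng, trial_id=i, start_frame=frame
        )
        pieces.append(trajs)
        records.append(rec)
        frame = rec["end_frame"] + (gap if i < n_trials - 1 else 0)

    n_frames = records[-1]["end_frame"]
    out_vars = ["self", "chosen_prey", "unchosen_prey", "predator"]

    xs = {v: np.full(n_frames, np.nan) for v in out_vars}
    ys = {v: np.full(n_frames, np.nan) for v in out_vars}
    ok = {v: np.zeros(n_frames, dtype=bool) for v in out_vars}
    for trajs, rec in zip(pieces, records):
        s, e = rec["start_frame"], rec["end_frame"]
        chosen = int(rec["chosen_prey_id"])
        mapping = {"self": "self", "predator": "predator"}
        mapping["chosen_prey"] = f"prey_{chosen}"
        if config.n_prey == 2:
            mapping["unchosen_prey"] = f"prey_{1 - chosen}"
        for out_name, src_name in mapping.items():
            src = trajs[src_name]
            xs[out_name][s:e] = src.x
            ys[out_name][s:e] = src.y
            ok[out_name][s:e] = src.valid

    frames = np.arange(n_frames)
    t_s = frames * config.frame_dt
    trajectories = {
        v: Trajectory(v, frames, t_s, xs[v], ys[v], ok[v]) for v in out_vars
    }
    return Session(
        trajectories=trajectories,
        trials=make_trials_frame(records),
        spikes=None,
        frame_dt=config.frame_dt,
        field_size=(config.field_width, config.field_height),
        meta={"seed": seed, "policy": policy, "n_trials": n_trials},
    )


# ---------------------------------------------------------------------------
# Planted populations
# ---------------------------------------------------------------------------


class SpecificationError(ValueError):
    """Raised when a requested planted geometry is infeasible."""


@dataclass(frozen=True)
class GeometrySpec:
    """Planted population geometry for a set of spatial variables.

    ``angles_deg`` plants the principal angles between each non-reference
    variable's latent subspace and the reference (first) variable's subspace;
    a scalar applies the same angle to every latent dimension.

    ``linear_map`` optionally ties a pair of variables' latent coordinates by
    ``A_b = W_true @ A_a`` (exact before noise).

    ``axis_relation`` plants, per non-reference variable, how its left/right
    decoding axis in neuron space relates to the reference's:
    ``shared`` (same direction), ``inverted`` (negated), ``orthogonal``.
    """

    variables: tuple[str, ...] = ("self", "chosen_prey")
    latent_dim: int = 4
    angles_deg: dict[str, float | tuple[float, ...]] = field(default_factory=dict)
    linear_map: tuple[str, str, np.ndarray] | None = None
    axis_relation: dict[str, str] = field(default_factory=dict)
    axis_gain: float = 0.0  # strength of the planted left/right component
    map_gain: float = 1.0  # scale of latent spatial patterns (log-rate units)
    noise_sd: float = 0.0  # additive map noise in neuron space


@dataclass
class GroundTruthPopulation:
    """Planted log-linear population: weight maps + geometry bookkeeping.

    ``weight_maps[variable]`` is an (n_neurons, 36) matrix of log-rate
    contributions; the nominal firing rate of neuron i at frame t is
    ``exp(log_baseline[i] + sum_v weight_maps[v][i, bin_v(t)])`` in Hz.
    """

    n_neurons: int
    weight_maps: dict[str, np.ndarray]
    tuned_variables: list[set[str]]
    baseline_rate: np.ndarray  # Hz per neuron
    latent_bases: dict[str, np.ndarray]  # neuron-space orthonormal (N, d)
    latent_coords: dict[str, np.ndarray]  # (d, 36)
    axis_vectors: dict[str, np.ndarray]  # unit left/right axis per variable
    spec: GeometrySpec
    seed: int

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.weight_maps)

    @property
    def log_baseline(self) -> np.ndarray:
        return np.log(self.baseline_rate)


def _smooth_latent_patterns(
    d: int, grid: Grid, rng: np.random.Generator
) -> np.ndarray:
    """(d, n_bins) smooth, mutually orthogonal spatial patterns of equal norm.

    Built from random mixtures of low-frequency 2-D cosine modes, then
    orthonormalized so that latent covariance is isotropic (this makes the
    planted subspace geometry exactly recoverable from map covariances).
    """
    rows, cols = grid.n_rows, grid.n_cols
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    modes = []
    for fr in range(3):
        for fc in range(3):
            if fr == fc == 0:
                continue
            m = np.cos(np.pi * fr * (rr + 0.5) / rows) * np.cos(
                np.pi * fc * (cc + 0.5) / cols
            )
            modes.append(m.ravel())
    modes = np.array(modes)  # (8, n_bins), each zero-mean
    if d > modes.shape[0]:
        raise SpecificationError(f"latent_dim must be <= {modes.shape[0]}")
    mix = rng.standard_normal((d, modes.shape[0]))
    patterns = mix @ modes
    # orthonormalize rows, then rescale to a common norm
    q, _ = np.linalg.qr(patterns.T)
    return q.T[:d] * math.sqrt(grid.n_bins)


def _lr_contrast(grid: Grid) -> np.ndarray:
    """Unit-norm left/right contrast over bins: -1 left columns, +1 right."""
    col = grid.column_of(np.arange(grid.n_bins))
    c = np.where(col >= grid.n_cols / 2.0, 1.0, -1.0)
    return c / np.linalg.norm(c)


def plant_population(
    geometry_spec: GeometrySpec,
    n_neurons: int = 100,
    seed: int = 0,
    grid: Grid = Grid(),
    baseline_rate_range: tuple[float, float] = (2.0, 8.0),
    untuned_fraction: float = 0.0,
) -> GroundTruthPopulation:
    """Construct a population whose map matrices realize the planted geometry.

    Per variable v, the (N x 36) weight-map matrix is
    ``M_v = map_gain * Q_v @ A_v + axis_gain * u_v @ c^T + noise`` where the
    neuron-space bases Q_v realize the requested principal angles against the
    reference variable, A_v are smooth orthonormal latent patterns, u_v the
    planted decoding axes and c the left/right bin contrast.
    """
    spec = geometry_spec
    d = spec.latent_dim
    n_vars = len(spec.variables)
    if d > grid.n_bins or d > n_neurons:
        raise SpecificationError("latent_dim must be <= n_bins and <= n_neurons")
    # reference basis + one fresh complement block per other variable + axes
    need = d * n_vars + n_vars
    if need > n_neurons:
        raise SpecificationError(
            f"need at least {need} neurons for {n_vars} variables at dim {d}"
        )
    for v, ang in spec.angles_deg.items():
        arr = np.atleast_1d(np.asarray(ang, dtype=float))
        if np.any(arr < 0) or np.any(arr > 90):
            raise SpecificationError("planted angles must lie in [0, 90] degrees")
        if arr.size not in (1, d):
            raise SpecificationError("angles must be scalar or one per latent dim")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    # one shared orthonormal frame in neuron space
    E, _ = np.linalg.qr(rng.standard_normal((n_neurons, need)))
    ref = spec.variables[0]
    bases: dict[str, np.ndarray] = {ref: E[:, :d]}
    axes: dict[str, np.ndarray] = {ref: E[:, d * n_vars]}
    for j, v in enumerate(spec.variables[1:], start=1):
        comp = E[:, d * j : d * (j + 1)]  # orthogonal to the reference basis
        ang = np.atleast_1d(
            np.asarray(spec.angles_deg.get(v, 90.0), dtype=float)
        )
        theta = np.deg2rad(np.broadcast_to(ang, (d,)))
        bases[v] = bases[ref] * np.cos(theta) + comp * np.sin(theta)
        rel = spec.axis_relation.get(v, "orthogonal")
        if rel == "shared":
            axes[v] = axes[ref]
        elif rel == "inverted":
            axes[v] = -axes[ref]
        elif rel == "orthogonal":
            axes[v] = E[:, d * n_vars + j]
        else:
            raise SpecificationError(f"unknown axis relation {rel!r}")

    # latent spatial coordinates
    coords: dict[str, np.ndarray] = {}
    for v in spec.variables:
        coords[v] = _smooth_latent_patterns(d, grid, rng)
    if spec.linear_map is not None:
        a, b, w_true = spec.linear_map
        w_true = np.asarray(w_true, dtype=float)
        if a not in coords or b not in coords:
            raise SpecificationError("linear_map references an unknown variable")
        if w_true.shape != (d, d):
            raise SpecificationError("W_true must be latent_dim x latent_dim")
        coords[b] = w_true @ coords[a]

    c_lr = _lr_contrast(grid)
    if spec.axis_gain:
        # the planted axis owns the left/right contrast: remove any such
        # contrast from the latent spatial patterns so transfer tests see
        # only the planted axis relation
        for v in spec.variables:
            coords[v] = coords[v] - np.outer(coords[v] @ c_lr, c_lr)
    weight_maps: dict[str, np.ndarray] = {}
    for v in spec.variables:
        m = spec.map_gain * bases[v] @ coords[v]
        if spec.axis_gain:
            m = m + spec.axis_gain * np.outer(axes[v], c_lr)
        if spec.noise_sd:
            m = m + spec.noise_sd * rng.standard_normal(m.shape)
        weight_maps[v] = m

    tuned = [set(spec.variables) for _ in range(n_neurons)]
    if untuned_fraction:
        n_untuned = int(round(untuned_fraction * n_neurons))
        for i in range(n_neurons - n_untuned, n_neurons):
            tuned[i] = set()
            for v in spec.variables:
                weight_maps[v][i] = 0.0

    lo, hi = baseline_rate_range
    baseline = rng.uniform(lo, hi, size=n_neurons)
    return GroundTruthPopulation(
        n_neurons=n_neurons,
        weight_maps=weight_maps,
        tuned_variables=tuned,
        baseline_rate=baseline,
        latent_bases=bases,
        latent_coords=coords,
        axis_vectors=axes,
        spec=spec,
        seed=seed,
    )


def untuned_population(
    n_neurons: int,
    variables: tuple[str, ...] = ("self", "chosen_prey"),
    seed: int = 0,
    baseline_rate_range: tuple[float, float] = (2.0, 8.0),
) -> GroundTruthPopulation:
    """Constant-rate population: every weight map identically zero."""
    grid = Grid()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo, hi = baseline_rate_range
    spec = GeometrySpec(variables=variables, latent_dim=1, map_gain=0.0)
    return GroundTruthPopulation(
        n_neurons=n_neurons,
        weight_maps={v: np.zeros((n_neurons, grid.n_bins)) for v in variables},
        tuned_variables=[set() for _ in range(n_neurons)],
        baseline_rate=rng.uniform(lo, hi, size=n_neurons),
        latent_bases={},
        latent_coords={},
        axis_vectors={},
        spec=spec,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Spikes and gaze
# ---------------------------------------------------------------------------


def simulate_spikes(
    session: Session,
    population: GroundTruthPopulation,
    seed: int = 0,
    grid: Grid | None = None,
    rate_ceiling: float = 200.0,
) -> SpikeMatrix:
    """Draw Poisson spike counts from the planted log-linear model.

    Frames where a tuned variable's position is invalid contribute baseline
    rate only (that variable's term is dropped for those frames).
    """
    if grid is None:
        grid = Grid(*session.field_size)
    n_frames = session.n_frames
    n = population.n_neurons
    if n_frames == 0:
        return SpikeMatrix(np.zeros((0, n), dtype=np.int64), session.frame_dt)

    bin_idx = {}
    for v in population.variables:
        if v not in session.trajectories:
            raise KeyError(f"session lacks variable {v!r} required by population")
        tr = session.trajectories[v]
        b = grid.bin_index(tr.x, tr.y)
        b[~tr.valid] = -1
        bin_idx[v] = b

    log_rate = np.tile(population.log_baseline, (n_frames, 1))  # (T, N)
    for v in population.variables:
        w = population.weight_maps[v]  # (N, 36)
        b = bin_idx[v]
        ok = b >= 0
        log_rate[ok] += w[:, b[ok]].T
    rate = np.exp(log_rate)
    np.minimum(rate, rate_ceiling, out=rate)

    # independent stream per neuron so adding neurons never perturbs others
    streams = np.random.SeedSequence(seed).spawn(n)
    counts = np.empty((n_frames, n), dtype=np.int64)
    for i in range(n):
        rng = np.random.default_rng(streams[i])
        counts[:, i] = rng.poisson(rate[:, i] * session.frame_dt)
    return SpikeMatrix(counts, session.frame_dt)


@dataclass(frozen=True)
class GazeParams:
    follow_weights: dict[str, float] = field(
        default_factory=lambda: {"self": 0.4, "chosen_prey": 0.6}
    )
    switch_rate: float = 1.0  # target switches per second
    jitter_sd: float = 20.0  # px
    dropout_prob: float = 0.05

    def __post_init__(self) -> None:
        w = np.array(list(self.follow_weights.values()), dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("follow weights must be >= 0 and sum > 0")


def simulate_gaze(
    session: Session, params: GazeParams = GazeParams(), seed: int = 0
) -> Trajectory:
    """Markov target-switching gaze with isotropic jitter and dropout.

    The gaze sits on a currently-followed agent (switching targets as a
    Poisson process at ``switch_rate``), plus Gaussian jitter, clipped to the
    screen; each frame independently drops out with ``dropout_prob``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_frames = session.n_frames
    targets = list(params.follow_weights)
    weights = np.array([params.follow_weights[t] for t in targets], dtype=float)
    weights = weights / weights.sum()

    current = rng.choice(len(targets), p=weights)
    p_switch = min(1.0, params.switch_rate * session.frame_dt)
    x = np.full(n_frames, np.nan)
    y = np.full(n_frames, np.nan)
    valid = np.zeros(n_frames, dtype=bool)
    w_, h_ = session.field_size
    for t in range(n_frames):
        if rng.random() < p_switch:
            current = rng.choice(len(targets), p=weights)
        src = session.trajectories[targets[current]]
        if not src.valid[t]:
            continue
        gx = src.x[t] + params.jitter_sd * rng.standard_normal()
        gy = src.y[t] + params.jitter_sd * rng.standard_normal()
        if rng.random() < params.dropout_prob:
            continue
        x[t] = min(max(gx, 0.0), w_)
        y[t] = min(max(gy, 0.0), h_)
        valid[t] = True
    frames = np.arange(n_frames)
    return Trajectory("gaze", frames, frames * session.frame_dt, x, y, valid)


def random_walk_session(
    n_frames: int,
    variables: tuple[str, ...] = ("self", "chosen_prey"),
    seed: int = 0,
    config: TaskConfig = TaskConfig(),
    step_sd: float = 25.0,
    trial_frames: int = 300,
) -> Session:
    """Session whose variables follow *independent* reflected random walks.

    Unlike the pursuit simulator, trajectories are mutually independent, so
    one variable's tuning cannot leak into another's rate map through
    behavioral correlation.  Frames are segmented into back-to-back pseudo
    trials, all marked captured, so trial-based resampling works unchanged.
    Useful as a null/controlled fixture for the statistical analyses.
    """
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(variables))
    w_, h_ = config.field_width, config.field_height
    frames = np.arange(n_frames)
    t_s = frames * config.frame_dt
    trajectories: dict[str, Trajectory] = {}
    for v, s in zip(variables, streams):
        rng = np.random.default_rng(s)
        start = rng.uniform([0.0, 0.0], [w_, h_])
        steps = step_sd * rng.standard_normal((n_frames, 2))
        pos = np.cumsum(steps, axis=0) + start
        # reflect into the field
        pos[:, 0] = np.abs(np.mod(pos[:, 0], 2 * w_) - w_)
        pos[:, 1] = np.abs(np.mod(pos[:, 1], 2 * h_) - h_)
        trajectories[v] = Trajectory(
            v, frames, t_s, pos[:, 0], pos[:, 1], np.ones(n_frames, bool)
        )
    records = []
    n_trials = max(1, n_frames // trial_frames)
    for i in range(n_trials):
        start = i * trial_frames
        end = n_frames if i == n_trials - 1 else (i + 1) * trial_frames
        records.append(
            {
                "trial_id": i,
                "start_frame": start,
                "end_frame": end,
                "outcome": "captured",
                "chosen_prey_id": 0,
                "reward": 1,
            }
        )
    return Session(
        trajectories=trajectories,
        trials=make_trials_frame(records),
        spikes=None,
        frame_dt=config.frame_dt,
        field_size=(w_, h_),
        meta={"seed": seed, "kind": "random_walk"},
    )


def attach_gaze(session: Session, gaze: Trajectory) -> Session:
    """Return a session with the gaze trajectory added."""
    trajectories = dict(session.trajectories)
    trajectories["gaze"] = gaze
    return replace(session, trajectories=trajectories)
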