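"""Cross-condition generalization performance (CCGP) of left/right position.

The concatenated captured trials are cut into non-overlapping 40 s chunks;
each chunk yields one population firing-rate vector per spatial bin and
variable.  Left/right classes use the 6 highest-occupancy bins among the 12
most leftward / most rightward grid bins.  A linear maximum-margin
classifier (SVM) trained on one variable's design is tested, without
retraining, on another variable's rows that share the held-out (chunk, bin)
structure: above-chance transfer means a shared (abstract) left/right coding
axis, below-chance an inverted axis.  Decoding-axis angles and their
classical-MDS embedding summarize the population geometry of the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core import Session
from .grid import Grid


class DesignError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------


@dataclass
class SessionChunks:
    variables: tuple[str, ...]
    n_chunks: int
    chunk_s: float
    rates: dict[str, np.ndarray]  # variable -> (n_chunks, n_bins, N) Hz
    occupancy: dict[str, np.ndarray]  # variable -> (n_chunks, n_bins) frames
    session_occupancy: dict[str, np.ndarray]  # variable -> (n_bins,)
    grid: Grid
    discarded_s: float = 0.0


def chunk_session(
    session: Session,
    chunk_s: float = 40.0,
    variables: tuple[str, ...] | None = None,
    grid: Grid | None = None,
) -> SessionChunks:
    """Per-chunk, per-variable mean-rate vectors over concatenated captured
    trials; a trailing remainder shorter than ``chunk_s`` is discarded."""
    if session.spikes is None:
        raise ValueError("session has no spikes")
    if grid is None:
        grid = Grid(*session.field_size)
    if variables is None:
        variables = tuple(session.trajectories)
    keep = session.trial_mask("captured")
    frames = np.flatnonzero(keep)
    chunk_frames = int(round(chunk_s / session.frame_dt))
    n_chunks = len(frames) // chunk_frames
    if n_chunks < 2:
        raise DesignError("need at least two chunks of concatenated data")
    used = frames[: n_chunks * chunk_frames]
    chunk_of = np.repeat(np.arange(n_chunks), chunk_frames)
    counts = session.spikes.counts[used]  # (F, N)
    n_bins = grid.n_bins
    nn = counts.shape[1]
    rates: dict[str, np.ndarray] = {}
    occs: dict[str, np.ndarray] = {}
    soccs: dict[str, np.ndarray] = {}
    for v in variables:
        tr = session.trajectories[v]
        b = grid.bin_index(tr.x, tr.y)
        b = np.where(tr.valid, b, -1)[used]
        ok = b >= 0
        flat = chunk_of[ok] * n_bins + b[ok]
        occ = np.bincount(flat, minlength=n_chunks * n_bins).reshape(
            n_chunks, n_bins
        )
        tot = np.zeros((n_chunks * n_bins, nn))
        np.add.at(tot, flat, counts[ok])
        tot = tot.reshape(n_chunks, n_bins, nn)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = tot / (occ[..., None] * session.frame_dt)
        rate[occ == 0] = np.nan
        rates[v] = rate
        occs[v] = occ
        soccs[v] = occ.sum(axis=0)
    discarded = (len(frames) - len(used)) * session.frame_dt
    return SessionChunks(
        variables=variables,
        n_chunks=n_chunks,
        chunk_s=chunk_s,
        rates=rates,
        occupancy=occs,
        session_occupancy=soccs,
        grid=grid,
        discarded_s=discarded,
    )


# ---------------------------------------------------------------------------
# Designs
# ---------------------------------------------------------------------------


@dataclass
class CcgpDesign:
    variable_id: str
    X: np.ndarray  # (rows, N) firing rates
    labels: np.ndarray  # (rows,) 0 = left, 1 = right
    chunk_ids: np.ndarray
    bin_ids: np.ndarray
    selected_bins: dict[str, np.ndarray]  # 'left'/'right' -> 6 bin indices
    n_dropped: int = 0

    @property
    def keys(self) -> np.ndarray:
        """(rows,) composite (chunk, bin) key for cross-context pairing."""
        return self.chunk_ids * 10_000 + self.bin_ids


def select_side_bins(
    grid: Grid, session_occupancy: np.ndarray, n_per_side: int = 6
) -> dict[str, np.ndarray]:
    """Among the 12 most leftward / rightward bins (grid columns {0,1} and
    {n-2, n-1}), keep the ``n_per_side`` with highest whole-session
    occupancy; ties broken by ascending bin index."""
    cols = grid.column_of(np.arange(grid.n_bins))
    out = {}
    for side, cand_cols in (("left", (0, 1)), ("right", (grid.n_cols - 2,
                                                         grid.n_cols - 1))):
        cand = np.flatnonzero(np.isin(cols, cand_cols))
        # stable sort on -occupancy keeps ascending-index tie-break
        order = np.argsort(-session_occupancy[cand], kind="stable")
        out[side] = np.sort(cand[order[:n_per_side]])
    return out


def build_ccgp_design(
    chunks: SessionChunks,
    variable: str,
    n_bins_side: int = 6,
    bin_rule: str = "occupancy",
    seed: int = 0,
) -> CcgpDesign:
    """Stack per-(chunk, selected bin) population vectors with L/R labels.

    ``bin_rule='random'`` picks 6 random bins per side instead of the
    highest-occupancy rule (a robustness option).  Rows whose bin was never
    visited in a chunk are dropped and counted.
    """
    if variable not in chunks.rates:
        raise DesignError(f"variable {variable!r} not chunked")
    grid = chunks.grid
    if bin_rule == "occupancy":
        selected = select_side_bins(grid, chunks.session_occupancy[variable],
                                    n_bins_side)
    elif bin_rule == "random":
        rng = np.random.default_rng(seed)
        cols = grid.column_of(np.arange(grid.n_bins))
        selected = {}
        for side, cand_cols in (("left", (0, 1)),
                                ("right", (grid.n_cols - 2, grid.n_cols - 1))):
            cand = np.flatnonzero(np.isin(cols, cand_cols))
            selected[side] = np.sort(rng.choice(cand, n_bins_side, replace=False))
    else:
        raise DesignError(f"unknown bin rule {bin_rule!r}")

    rows, labels, chunk_ids, bin_ids = [], [], [], []
    dropped = 0
    for c in range(chunks.n_chunks):
        for side, lab in (("left", 0), ("right", 1)):
            for b in selected[side]:
                vec = chunks.rates[variable][c, b]
                if np.any(np.isnan(vec)):
                    dropped += 1
                    continue
                rows.append(vec)
                labels.append(lab)
                chunk_ids.append(c)
                bin_ids.append(b)
    if not rows:
        raise DesignError("empty CCGP design")
    return CcgpDesign(
        variable_id=variable,
        X=np.array(rows),
        labels=np.array(labels),
        chunk_ids=np.array(chunk_ids),
        bin_ids=np.array(bin_ids),
        selected_bins=selected,
        n_dropped=dropped,
    )


# ---------------------------------------------------------------------------
# CCGP computation
# ---------------------------------------------------------------------------


@dataclass
class CcgpResult:
    train: str
    test: str
    ccgp: float
    per_rep: np.ndarray
    null: np.ndarray | None = None
    p: float | None = None
    direction: str | None = None  # above | below | at chance


def _zstats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def _ccgp_once(
    train: CcgpDesign,
    test: CcgpDesign,
    rng: np.random.Generator,
    train_frac: float,
    svm_c: float,
    labels_train: np.ndarray,
    labels_test: np.ndarray,
    max_retries: int = 20,
) -> float:
    n = len(labels_train)
    for _ in range(max_retries):
        held = np.zeros(n, dtype=bool)
        for lab in (0, 1):
            idx = np.flatnonzero(labels_train == lab)
            n_held = max(1, int(round(len(idx) * (1.0 - train_frac))))
            held[rng.choice(idx, size=n_held, replace=False)] = True
        tr = ~held
        if len(np.unique(labels_train[tr])) == 2:
            break
    else:
        raise DesignError("could not build a class-balanced split")
    mu, sd = _zstats(train.X[tr])
    clf = SVC(kernel="linear", C=svm_c)
    clf.fit((train.X[tr] - mu) / sd, labels_train[tr])
    held_keys = train.keys[held]
    te = np.isin(test.keys, held_keys)
    if not te.any():  # disjoint row structure: fall back to all test rows
        te = np.ones(len(labels_test), dtype=bool)
    pred = clf.predict((test.X[te] - mu) / sd)
    return float(np.mean(pred == labels_test[te]))


def ccgp(
    train: CcgpDesign,
    test: CcgpDesign,
    n_reps: int = 50,
    train_frac: float = 0.7,
    seed: int = 0,
    svm_c: float = 1.0,
    _labels: tuple[np.ndarray, np.ndarray] | None = None,
) -> CcgpResult:
    """Mean cross-context classification accuracy over random 70/30 splits.

    Per repetition: class-balanced split of the training design, per-neuron
    z-scoring with training-rows statistics only (applied unchanged to the
    test context), linear SVM fit, accuracy on the test-context rows whose
    (chunk, bin) keys fall in the held-out part.
    """
    if train.X.shape[1] != test.X.shape[1]:
        raise DesignError("designs differ in neuron count")
    labels_train, labels_test = (
        _labels if _labels is not None else (train.labels, test.labels)
    )
    rng = np.random.default_rng(seed)
    accs = np.array(
        [
            _ccgp_once(train, test, rng, train_frac, svm_c,
                       labels_train, labels_test)
            for _ in range(n_reps)
        ]
    )
    return CcgpResult(
        train=train.variable_id,
        test=test.variable_id,
        ccgp=float(accs.mean()),
        per_rep=accs,
    )


def ccgp_null(
    train: CcgpDesign,
    test: CcgpDesign,
    n_shuffles: int = 500,
    n_reps: int = 50,
    train_frac: float = 0.7,
    seed: int = 0,
    svm_c: float = 1.0,
) -> CcgpResult:
    """CCGP with a label-shuffle null and a directional tail p-value.

    Left/right labels are independently permuted within each context; the
    full repetition procedure is re-run per shuffle.  p is the tail fraction
    in the direction of the observed deviation from chance (0.5), with a +1
    correction; ``direction`` records above/below/at chance at alpha=0.05.
    """
    ss = np.random.SeedSequence(seed)
    s_obs, s_null = ss.spawn(2)
    obs = ccgp(train, test, n_reps=n_reps, train_frac=train_frac,
               seed=s_obs, svm_c=svm_c)
    rng = np.random.default_rng(s_null)
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        lt = rng.permutation(train.labels)
        le = rng.permutation(test.labels)
        null[i] = ccgp(
            train, test, n_reps=n_reps, train_frac=train_frac,
            seed=np.random.default_rng(rng.integers(2**31)), svm_c=svm_c,
            _labels=(lt, le),
        ).ccgp
    if obs.ccgp >= 0.5:
        p = (np.sum(null >= obs.ccgp) + 1.0) / (n_shuffles + 1.0)
        direction = "above" if p < 0.05 else "at chance"
    else:
        p = (np.sum(null <= obs.ccgp) + 1.0) / (n_shuffles + 1.0)
        direction = "below" if p < 0.05 else "at chance"
    obs.null = null
    obs.p = float(p)
    obs.direction = direction
    return obs


# ---------------------------------------------------------------------------
# Decoding-axis geometry
# ---------------------------------------------------------------------------


@dataclass
class AxisGeometry:
    variables: tuple[str, ...]
    axes: np.ndarray  # (V, N) unit weight vectors
    cosines: np.ndarray  # (V, V)
    angles_deg: np.ndarray
    distances: np.ndarray  # sqrt(2 (1 - cos))
    mds_coords: np.ndarray  # (V, 2), arbitrary rotation/reflection


def classical_mds(d: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Torgerson MDS: double-center the squared distances, eigendecompose."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_dims]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def axis_geometry(designs: dict[str, CcgpDesign], svm_c: float = 1.0) -> AxisGeometry:
    """One decoding axis per variable; pairwise angles and MDS embedding.

    Each axis is the weight vector of a linear SVM trained on the variable's
    full z-scored design, normalized to unit length.
    """
    if len(designs) < 2:
        raise ValueError("need at least two variables")
    names = tuple(designs)
    axes = []
    for v in names:
        d = designs[v]
        mu, sd = _zstats(d.X)
        clf = SVC(kernel="linear", C=svm_c)
        clf.fit((d.X - mu) / sd, d.labels)
        w = clf.coef_.ravel()
        norm = np.linalg.norm(w)
        if norm < 1e-12:
            raise ValueError(f"degenerate decoding axis for {v!r}")
        axes.append(w / norm)
    axes = np.array(axes)
    cos = np.clip(axes @ axes.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cos))
    dist = np.sqrt(np.clip(2.0 * (1.0 - cos), 0.0, None))
    np.fill_diagonal(dist, 0.0)
    coords = classical_mds(dist)
    return AxisGeometry(
        variables=names,
        axes=axes,
        cosines=cos,
        angles_deg=ang,
        distances=dist,
        mds_coords=coords,
    )
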