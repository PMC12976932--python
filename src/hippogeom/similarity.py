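"""Map-level similarity statistics between spatial variables.

SPAEF (spatial efficiency) scores the similarity of two rate maps by
combining their Pearson correlation (A), the ratio of their coefficients of
variation (B), and the histogram intersection of their z-scored values (C):

    SPAEF = 1 - sqrt((A - 1)^2 + (B - 1)^2 + (C - 1)^2)

1 means perfect matching; values near 0, unrelated maps.  The agent
preference index (API) contrasts a neuron's tuning strength (95th-5th
percentile range of its unnormalized map) between two variables, each
normalized by the population-mean strength for that variable; a bimodal API
distribution would indicate segregated neuron pools (Hartigan dip test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage

from ._dip import dip_test
from .core import Session
from .grid import Grid
from .maps import BinSeries, PopulationMatrix, bin_position, stack_rate_maps


class DegenerateMapError(ValueError):
    """A constant map has no coefficient of variation."""


@dataclass
class SpaefComponents:
    A: float  # Pearson correlation
    B: float  # cv(map_b) / cv(map_a)
    C: float  # histogram intersection of z-scored maps
    spaef: float


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def spaef(
    map_a: np.ndarray, map_b: np.ndarray, hist_bins: int = 10
) -> SpaefComponents:
    """SPAEF between two vectorized maps (order-sensitive in B: cv_b/cv_a).

    Maps should be smoothed but unnormalized (B needs real coefficients of
    variation); z-scoring happens only inside the histogram component, whose
    bins are equal-width over the union range of both z-scored maps.
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps differ in size")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateMapError("constant map: cv undefined")
    # identical maps correlate exactly 1 (np.corrcoef rounds to 1 - eps)
    A = 1.0 if np.array_equal(a, b) else float(np.corrcoef(a, b)[0, 1])
    cv_a = a.std(ddof=1) / a.mean() if a.mean() != 0 else np.inf
    cv_b = b.std(ddof=1) / b.mean() if b.mean() != 0 else np.inf
    B = float(cv_b / cv_a)
    za, zb = _zscore(a), _zscore(b)
    lo = min(za.min(), zb.min())
    hi = max(za.max(), zb.max())
    edges = np.linspace(lo, hi, hist_bins + 1)
    ha, _ = np.histogram(za, bins=edges)
    hb, _ = np.histogram(zb, bins=edges)
    C = float(np.minimum(ha, hb).sum() / ha.sum())
    val = 1.0 - np.sqrt((A - 1.0) ** 2 + (B - 1.0) ** 2 + (C - 1.0) ** 2)
    return SpaefComponents(A=A, B=B, C=C, spaef=float(val))


def spaef_permutation_p(
    map_a: np.ndarray,
    map_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    hist_bins: int = 10,
) -> tuple[float, float]:
    """Two-sided permutation p for SPAEF against bin-shuffled maps.

    Only the second map's bins are permuted (the first map's marginal is
    preserved exactly).  Returns (observed spaef, p) with a +1 correction.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    b = np.asarray(map_b, dtype=float).ravel()
    obs = spaef(map_a, map_b, hist_bins).spaef
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = spaef(map_a, b[rng.permutation(len(b))], hist_bins).spaef
    p = (np.sum(np.abs(null) >= abs(obs)) + 1.0) / (n_perm + 1.0)
    return obs, float(p)


def _half_split_maps(
    session: Session,
    variable: str,
    rng: np.random.Generator,
    grid: Grid,
    smoothing_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw map stacks (N, n_bins) from two disjoint halves of the captured
    trials (odd trial out dropped)."""
    trials = session.trials
    ok = trials[trials["outcome"] == "captured"]
    order = rng.permutation(len(ok))
    half = len(ok) // 2
    out = []
    traj = session.trajectories[variable]
    base = bin_position(traj, grid, session=None, trial_filter=None)
    for sel in (order[:half], order[half : 2 * half]):
        mask = np.zeros(session.n_frames, dtype=bool)
        for _, row in ok.iloc[sel].iterrows():
            mask[int(row["start_frame"]) : int(row["end_frame"])] = True
        bins = BinSeries(variable, np.where(mask, base.bins, -1), grid)
        raw, _ = stack_rate_maps(session.spikes, bins, smoothing_sd)
        out.append(raw)
    return out[0], out[1]


def spaef_noise_ceiling(
    session: Session,
    variable: str,
    n_splits: int = 1000,
    seed: int = 0,
    grid: Grid | None = None,
    smoothing_sd: float = 0.5,
    hist_bins: int = 10,
) -> tuple[np.ndarray, float]:
    """Within-variable half-split SPAEF ceiling, per neuron and mean.

    Captured trials are randomly split into two disjoint halves ``n_splits``
    times; the ceiling is each neuron's mean SPAEF between the two
    half-session maps, an upper bound for any cross-variable similarity.
    """
    if grid is None:
        grid = Grid(*session.field_size)
    n_ok = int((session.trials["outcome"] == "captured").sum())
    if n_ok < 4:
        raise ValueError("need >= 4 captured trials for half-splits")
    rng = np.random.default_rng(seed)
    n_neurons = session.spikes.n_neurons
    total = np.zeros(n_neurons)
    count = np.zeros(n_neurons)
    for _ in range(n_splits):
        maps1, maps2 = _half_split_maps(session, variable, rng, grid, smoothing_sd)
        for i in range(n_neurons):
            try:
                total[i] += spaef(maps1[i], maps2[i], hist_bins).spaef
                count[i] += 1
            except DegenerateMapError:
                continue
    with np.errstate(invalid="ignore"):
        ceiling = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return ceiling, float(np.nanmean(ceiling))


# ---------------------------------------------------------------------------
# Agent preference index
# ---------------------------------------------------------------------------


@dataclass
class ApiResult:
    pair: tuple[str, str]
    api: np.ndarray  # per neuron, NaN where undefined
    n_excluded: int
    dip: float
    dip_p: float


def tuning_strength(raw_maps: np.ndarray) -> np.ndarray:
    """95th - 5th percentile range per row of an (N, n_bins) raw-map stack."""
    hi = np.percentile(raw_maps, 95, axis=1)
    lo = np.percentile(raw_maps, 5, axis=1)
    return hi - lo


def agent_preference_indices(
    raw_a: np.ndarray,
    raw_b: np.ndarray,
    pair: tuple[str, str] = ("a", "b"),
    n_boot: int = 2000,
    seed: int = 0,
) -> ApiResult:
    """API per neuron between two variables' unnormalized maps + dip test.

    api_i = S_a(i)/mean(S_a) - S_b(i)/mean(S_b).  Neurons with zero range in
    both maps are excluded (counted); the dip test for bimodality runs on
    the remaining values against a uniform bootstrap null.
    """
    raw_a = np.asarray(raw_a, float)
    raw_b = np.asarray(raw_b, float)
    if raw_a.shape != raw_b.shape:
        raise ValueError("map stacks differ in shape")
    if raw_a.shape[0] < 10:
        raise ValueError("need >= 10 neurons")
    s_a = tuning_strength(raw_a)
    s_b = tuning_strength(raw_b)
    dead = (s_a == 0) & (s_b == 0)
    api = np.full(len(s_a), np.nan)
    live = ~dead
    api[live] = s_a[live] / s_a[live].mean() - s_b[live] / s_b[live].mean()
    vals = api[live]
    if np.ptp(vals) == 0:
        dip, p = 0.0, 1.0  # point mass: unimodal by convention
    else:
        dip, p = dip_test(vals, n_boot=n_boot, seed=seed)
    return ApiResult(pair=pair, api=api, n_excluded=int(dead.sum()),
                     dip=dip, dip_p=p)


# ---------------------------------------------------------------------------
# Correlation-matrix structure
# ---------------------------------------------------------------------------


@dataclass
class CorrStructure:
    reference: str
    corr: dict[str, np.ndarray]  # variable -> N x N Pearson matrix
    leaf_order: np.ndarray
    cross_matrix_r2: dict[tuple[str, str], float]


def correlation_structure(
    matrices: dict[str, PopulationMatrix], reference: str
) -> CorrStructure:
    """Neuron-by-neuron correlation matrices, common leaf order, cross R^2.

    The display order comes from centroid-linkage hierarchical clustering of
    the reference variable's correlation matrix (Euclidean distance between
    its rows); similarity of correlation structure across variables is the
    squared Pearson correlation between upper-triangle vectors.
    """
    if reference not in matrices:
        raise ValueError(f"reference {reference!r} not among matrices")
    ids = None
    for v, pm in matrices.items():
        if ids is None:
            ids = pm.neuron_ids
        elif not np.array_equal(ids, pm.neuron_ids):
            raise ValueError("population matrices have mismatched neuron sets")
    corr = {v: np.corrcoef(pm.M) for v, pm in matrices.items()}
    z = linkage(corr[reference], method="centroid")
    order = leaves_list(z)
    iu = np.triu_indices(len(ids), k=1)
    names = list(matrices)
    r2 = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = np.corrcoef(corr[a][iu], corr[b][iu])[0, 1]
            r2[(a, b)] = float(r**2)
    return CorrStructure(
        reference=reference, corr=corr, leaf_order=order, cross_matrix_r2=r2
    )
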