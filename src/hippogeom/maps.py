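"""Occupancy-binned, smoothed spatial rate maps and population matrices.

For each neuron and each spatial variable the screen is discretized into a
6x6 grid; the mean firing rate per bin (over frames from successfully
captured trials) forms a rate map, smoothed with a small Gaussian kernel
(sigma = 0.5 bins).  Vectorized maps stacked across neurons, z-scored per
neuron, give the population matrix M in R^(N x 36) that feeds every
similarity / subspace / decoding analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Session, SpikeMatrix, Trajectory
from .grid import Grid

ZERO_VARIANCE_SD = 1e-12


class EmptySelectionError(ValueError):
    """Raised when a trial filter leaves no analyzable frames."""


@dataclass
class BinSeries:
    """Per-frame spatial bin index for one variable; -1 where missing."""

    variable_id: str
    bins: np.ndarray  # (T,) int, -1 = missing (invalid frame or filtered trial)
    grid: Grid

    def __len__(self) -> int:
        return len(self.bins)

    @property
    def included(self) -> np.ndarray:
        return self.bins >= 0


@dataclass
class RateMap:
    neuron_id: int
    variable_id: str
    values: np.ndarray  # (n_rows, n_cols) Hz, smoothed
    occupancy: np.ndarray  # (n_rows, n_cols) frame counts
    smoothing_sd: float
    imputed: np.ndarray | None = None  # bool mask of occupancy-zero bins

    @property
    def vector(self) -> np.ndarray:
        """Row-major 36-vector view of the map."""
        return self.values.ravel()


@dataclass
class PopulationMatrix:
    """Neurons x n_bins map matrix, rows z-scored across bins."""

    variable_id: str
    M: np.ndarray  # (N_kept, n_bins) z-scored
    neuron_ids: np.ndarray  # (N_kept,)
    raw: np.ndarray  # (N_kept, n_bins) unnormalized
    zero_variance_ids: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_neurons(self) -> int:
        return self.M.shape[0]


def bin_position(
    traj: Trajectory,
    grid: Grid,
    session: Session | None = None,
    trial_filter: str | None = "captured",
) -> BinSeries:
    """Bin a trajectory, restricted to frames of trials passing the filter.

    ``trial_filter`` is an outcome label (default: only successfully captured
    trials enter the analysis) or None to keep all trials.  Frames outside
    any retained trial, or with an invalid position, get bin -1.
    """
    bins = grid.bin_index(traj.x, traj.y)
    bins = np.where(traj.valid, bins, -1)
    if session is not None:
        keep = session.trial_mask(trial_filter)
        bins = np.where(keep, bins, -1)
    if not np.any(bins >= 0):
        raise EmptySelectionError(
            f"no analyzable frames for variable {traj.variable_id!r}"
        )
    return BinSeries(traj.variable_id, bins, grid)


def _gaussian_weights(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Per-bin total in-grid kernel weight (for edge renormalization)."""
    return ndimage.gaussian_filter(np.ones(shape), sigma=sigma, mode="constant")


def smooth_map(values: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with a truncated, mass-preserving boundary rule.

    Each bin's mass is spread over its in-grid neighbors with the kernel
    renormalized to the weight that stays on the grid (no wraparound: the
    screen is bounded).  Linear in the input and preserves the total sum.
    """
    if sigma <= 0:
        return values.copy()
    norm = _gaussian_weights(values.shape, sigma)
    return ndimage.gaussian_filter(values / norm, sigma=sigma, mode="constant")


def _impute_empty_bins(
    rate: np.ndarray, occupied: np.ndarray, sigma: float
) -> np.ndarray:
    """Fill unoccupied bins with the kernel-weighted mean of occupied ones."""
    sig = max(sigma, 0.5)  # even unsmoothed maps need a finite kernel to impute
    num = ndimage.gaussian_filter(
        np.where(occupied, rate, 0.0), sigma=sig, mode="constant"
    )
    den = ndimage.gaussian_filter(occupied.astype(float), sigma=sig, mode="constant")
    out = rate.copy()
    hole = ~occupied
    with np.errstate(invalid="ignore", divide="ignore"):
        fill = np.where(den > 0, num / den, 0.0)
    # kernel support may miss distant holes entirely; fall back to the mean
    fallback = rate[occupied].mean() if occupied.any() else 0.0
    out[hole] = np.where(den[hole] > 0, fill[hole], fallback)
    return out


def compute_rate_map(
    spikes: SpikeMatrix | np.ndarray,
    bins: BinSeries,
    neuron_id: int = 0,
    smoothing_sd: float = 0.5,
) -> RateMap:
    """Mean firing rate per bin (Hz), imputed where empty, then smoothed.

    ``spikes`` may be a SpikeMatrix (one column selected by ``neuron_id``) or
    a 1-D per-frame count array.
    """
    if isinstance(spikes, SpikeMatrix):
        counts = spikes.counts[:, neuron_id]
        dt = spikes.frame_dt
    else:
        raise TypeError("spikes must be a SpikeMatrix; pass counts via SpikeMatrix")
    if len(counts) != len(bins):
        raise ValueError("spike and bin series lengths differ")

    grid = bins.grid
    idx = bins.bins
    ok = idx >= 0
    if not ok.any():
        raise EmptySelectionError("all bins empty: nothing to map")
    occ = np.bincount(idx[ok], minlength=grid.n_bins).astype(float)
    tot = np.bincount(idx[ok], weights=counts[ok], minlength=grid.n_bins)
    shape = (grid.n_rows, grid.n_cols)
    occ2 = occ.reshape(shape)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ2 > 0, tot.reshape(shape) / (occ2 * dt), 0.0)
    occupied = occ2 > 0
    imputed = ~occupied
    if imputed.any():
        rate = _impute_empty_bins(rate, occupied, smoothing_sd)
    return RateMap(
        neuron_id=neuron_id,
        variable_id=bins.variable_id,
        values=smooth_map(rate, smoothing_sd),
        occupancy=occ2,
        smoothing_sd=smoothing_sd,
        imputed=imputed,
    )


def stack_rate_maps(
    spikes: SpikeMatrix, bins: BinSeries, smoothing_sd: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """All neurons' smoothed rate maps at once.

    Returns (raw maps (N, n_bins) in Hz, occupancy (n_bins,)); equivalent to
    per-neuron :func:`compute_rate_map` but vectorized over neurons (used by
    the resampling procedures that rebuild maps hundreds of times).
    """
    grid = bins.grid
    idx = bins.bins
    ok = idx >= 0
    if not ok.any():
        raise EmptySelectionError("all bins empty: nothing to map")
    occ = np.bincount(idx[ok], minlength=grid.n_bins).astype(float)
    n_neurons = spikes.n_neurons
    tot = np.zeros((grid.n_bins, n_neurons))
    np.add.at(tot, idx[ok], spikes.counts[ok])
    shape = (grid.n_rows, grid.n_cols)
    occ2 = occ.reshape(shape)
    occupied = occ2 > 0
    out = np.empty((n_neurons, grid.n_bins))
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(
            occ2[None] > 0,
            tot.T.reshape(n_neurons, *shape) / (occ2[None] * spikes.frame_dt),
            0.0,
        )
    for i in range(n_neurons):
        r = rates[i]
        if not occupied.all():
            r = _impute_empty_bins(r, occupied, smoothing_sd)
        out[i] = smooth_map(r, smoothing_sd).ravel()
    return out, occ


def session_rate_maps(
    session: Session,
    variable: str,
    grid: Grid | None = None,
    smoothing_sd: float = 0.5,
    trial_filter: str | None = "captured",
) -> list[RateMap]:
    """Rate maps for every neuron of a session, one spatial variable."""
    if session.spikes is None:
        raise ValueError("session has no spike matrix")
    if grid is None:
        grid = Grid(*session.field_size)
    bins = bin_position(
        session.trajectories[variable], grid, session=session, trial_filter=trial_filter
    )
    return [
        compute_rate_map(session.spikes, bins, neuron_id=i, smoothing_sd=smoothing_sd)
        for i in range(session.spikes.n_neurons)
    ]


def zscore_rows(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise z-score (ddof=1); returns (z, zero_variance_row_mask)."""
    mean = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] < ZERO_VARIANCE_SD
    safe = np.where(sd < ZERO_VARIANCE_SD, 1.0, sd)
    return (raw - mean) / safe, flat


def build_population_matrix(
    rate_maps: list[RateMap], drop_zero_variance: bool = True
) -> PopulationMatrix:
    """Stack vectorized maps across neurons and z-score each row.

    Rows with (numerically) constant maps carry no tuning information and are
    flagged; by default they are excluded from the matrix, with their ids
    recorded in ``zero_variance_ids``.
    """
    if not rate_maps:
        raise ValueError("no rate maps given")
    var = rate_maps[0].variable_id
    shape = rate_maps[0].values.shape
    ids = np.array([m.neuron_id for m in rate_maps])
    if len(np.unique(ids)) != len(ids):
        raise ValueError("duplicate neuron_id in rate map list")
    for m in rate_maps:
        if m.variable_id != var or m.values.shape != shape:
            raise ValueError("rate maps mix variables or grids")
    raw = np.stack([m.vector for m in rate_maps])
    z, flat = zscore_rows(raw)
    if drop_zero_variance:
        keep = ~flat
        return PopulationMatrix(
            variable_id=var,
            M=z[keep],
            neuron_ids=ids[keep],
            raw=raw[keep],
            zero_variance_ids=ids[flat],
        )
    return PopulationMatrix(
        variable_id=var, M=z, neuron_ids=ids, raw=raw,
        zero_variance_ids=ids[flat],
    )


def population_matrices(
    session: Session,
    variables: list[str],
    grid: Grid | None = None,
    smoothing_sd: float = 0.5,
    trial_filter: str | None = "captured",
) -> dict[str, PopulationMatrix]:
    """Population matrices for several variables, common neuron set.

    Neurons flagged zero-variance for *any* requested variable are dropped
    from all matrices so downstream pairwise analyses see one neuron set.
    """
    per_var = {
        v: session_rate_maps(session, v, grid, smoothing_sd, trial_filter)
        for v in variables
    }
    mats = {v: build_population_matrix(per_var[v], drop_zero_variance=False)
            for v in variables}
    flat_ids: set[int] = set()
    for pm in mats.values():
        flat_ids.update(pm.zero_variance_ids.tolist())
    out = {}
    for v, pm in mats.items():
        keep = ~np.isin(pm.neuron_ids, sorted(flat_ids))
        out[v] = PopulationMatrix(
            variable_id=v,
            M=pm.M[keep],
            neuron_ids=pm.neuron_ids[keep],
            raw=pm.raw[keep],
            zero_variance_ids=np.array(sorted(flat_ids), dtype=int),
        )
    return out


def maps_frame(rate_maps: list[RateMap]) -> pd.DataFrame:
    """Long-format export: neuron_id, variable, bin_index, rate, occupancy."""
    rows = []
    for m in rate_maps:
        imput = m.imputed.ravel() if m.imputed is not None else np.zeros(
            m.values.size, bool
        )
        for b in range(m.values.size):
            rows.append(
                {
                    "neuron_id": m.neuron_id,
                    "variable": m.variable_id,
                    "bin_index": b,
                    "rate_hz": m.values.ravel()[b],
                    "occupancy": int(m.occupancy.ravel()[b]),
                    "imputed_flag": bool(imput[b]),
                }
            )
    return pd.DataFrame(rows)
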