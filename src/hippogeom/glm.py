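"""Poisson linear-nonlinear GLM over one-hot position predictors.

Each spatial variable contributes a 36-column one-hot block (6x6 screen
grid); the expected spike count of a neuron in frame t is
``mu_t = exp(b + sum_v w_v[bin_v(t)])`` (firing rate ``mu_t / dt`` Hz).
Weights are fit by maximizing the Poisson log-likelihood minus a per-variable
smoothness penalty ``beta_v * w_v' L w_v`` (graph Laplacian of the 4-neighbor
grid, i.e. the sum of squared first differences along both screen axes).

Regularization strength is chosen by 10-fold cross-validation on the
spike-normalized log-likelihood increase over a mean-rate null (bits/spike),
and each neuron's tuned-variable set is found by forward stepwise selection
with a one-tailed exact Wilcoxon signed-rank test across folds.

Implementation notes: frames with identical one-hot rows are aggregated
(count + spike sum) before optimization — the Poisson likelihood only
depends on those sufficient statistics — and the convex penalized
likelihood is maximized by damped Newton iterations with analytic
gradient/Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .maps import BinSeries

LN2 = np.log(2.0)

DEFAULT_BETA_GRID = (1.0, 10.0, 100.0, 1000.0)
INTERCEPT_RIDGE = 1e-8
WEIGHT_RIDGE = 1e-8


class FitError(RuntimeError):
    """Optimizer failed to converge within the iteration budget."""


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Complete-case one-hot design for a set of spatial variables.

    Frames missing *any* requested variable are excluded.  ``combo_bins``
    enumerates the distinct joint bin configurations observed; ``combo_id``
    maps each included frame to its configuration, which is all the Poisson
    likelihood needs.
    """

    variables: tuple[str, ...]
    n_bins: int
    frame_index: np.ndarray  # (T_inc,) indices into the session frame base
    bin_idx: np.ndarray  # (T_inc, V)
    combo_id: np.ndarray  # (T_inc,) -> row of combo_bins
    combo_bins: np.ndarray  # (U, V)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    @property
    def n_params(self) -> int:
        return 1 + self.n_bins * len(self.variables)

    def block(self, v: str) -> slice:
        """Column slice of variable ``v`` in the parameter vector."""
        j = self.variables.index(v)
        return slice(1 + j * self.n_bins, 1 + (j + 1) * self.n_bins)

    def onehot(self, combo_rows: np.ndarray) -> np.ndarray:
        """Dense one-hot matrix (with leading intercept column) for combos."""
        u = len(combo_rows)
        x = np.zeros((u, self.n_params))
        x[:, 0] = 1.0
        for j in range(combo_rows.shape[1]):
            x[np.arange(u), 1 + j * self.n_bins + combo_rows[:, j]] = 1.0
        return x


def build_design_matrix(bin_series: list[BinSeries]) -> DesignMatrix:
    """Assemble a complete-case design from per-variable bin series."""
    if not bin_series:
        raise ValueError("need at least one bin series")
    n = len(bin_series[0])
    n_bins = bin_series[0].grid.n_bins
    for bs in bin_series:
        if len(bs) != n or bs.grid.n_bins != n_bins:
            raise ValueError("bin series do not share a frame base / grid")
    stacked = np.stack([bs.bins for bs in bin_series], axis=1)  # (T, V)
    keep = np.all(stacked >= 0, axis=1)
    if not keep.any():
        raise ValueError("no frame has all requested variables defined")
    bins = stacked[keep]
    combos, combo_id = np.unique(bins, axis=0, return_inverse=True)
    return DesignMatrix(
        variables=tuple(bs.variable_id for bs in bin_series),
        n_bins=n_bins,
        frame_index=np.flatnonzero(keep),
        bin_idx=bins,
        combo_id=combo_id,
        combo_bins=combos,
    )


def grid_laplacian(n_rows: int = 6, n_cols: int = 6) -> np.ndarray:
    """Graph Laplacian of the 4-neighbor grid (row-major), no wraparound.

    ``w' L w`` equals the sum of squared first differences between adjacent
    bins along both screen axes.
    """
    n = n_rows * n_cols
    lap = np.zeros((n, n))
    for r in range(n_rows):
        for c in range(n_cols):
            i = r * n_cols + c
            for rr, cc in ((r + 1, c), (r, c + 1)):
                if rr < n_rows and cc < n_cols:
                    j = rr * n_cols + cc
                    lap[i, i] += 1
                    lap[j, j] += 1
                    lap[i, j] -= 1
                    lap[j, i] -= 1
    return lap


# ---------------------------------------------------------------------------
# Penalized Poisson fitting
# ---------------------------------------------------------------------------


@dataclass
class GlmFit:
    variables: tuple[str, ...]
    intercept: float
    weights: dict[str, np.ndarray]
    beta: dict[str, float]
    dt: float
    cv_llh_increase: np.ndarray | None = None  # bits/spike per test fold
    pred_corr: float | None = None
    n_iter: int = 0

    @property
    def theta(self) -> np.ndarray:
        parts = [np.array([self.intercept])]
        parts.extend(self.weights[v] for v in self.variables)
        return np.concatenate(parts)

    def rate_hz(self, design: DesignMatrix) -> np.ndarray:
        """Predicted firing rate (Hz) per included frame."""
        eta = self._eta_frames(design)
        return np.exp(eta) / self.dt

    def _eta_frames(self, design: DesignMatrix) -> np.ndarray:
        eta = np.full(design.n_frames, self.intercept)
        for j, v in enumerate(design.variables):
            eta += self.weights[v][design.bin_idx[:, j]]
        return eta


def _penalty_matrix(
    design: DesignMatrix, beta: dict[str, float], lap: np.ndarray
) -> np.ndarray:
    """Quadratic penalty P such that the penalty term is theta' P theta."""
    p = design.n_params
    pen = np.zeros((p, p))
    pen[0, 0] = INTERCEPT_RIDGE
    for v in design.variables:
        sl = design.block(v)
        pen[sl, sl] = beta[v] * lap
    pen[np.diag_indices(p)] += WEIGHT_RIDGE
    pen[0, 0] -= WEIGHT_RIDGE  # intercept keeps its own small ridge only
    return pen


def _newton_poisson(
    x_u: np.ndarray,
    n_u: np.ndarray,
    s_u: np.ndarray,
    pen: np.ndarray,
    theta0: np.ndarray | None = None,
    max_iter: int = 200,
    gtol: float = 1e-6,
) -> tuple[np.ndarray, int]:
    """Minimize sum_u [n_u exp(eta_u) - s_u eta_u] + theta' P theta.

    Damped Newton with backtracking; the objective is convex so the iterates
    decrease monotonically.  ``eta`` is clipped at +30 inside the line search
    to avoid overflow on wild trial steps (never active at the optimum for
    count data).
    """
    p = x_u.shape[1]
    theta = np.zeros(p) if theta0 is None else theta0.copy()
    total = s_u.sum()
    if total > 0:  # warm start the intercept at the mean log-count
        theta = theta.copy()
        theta[0] = np.log(total / n_u.sum())

    def objective(th: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
        eta = np.clip(x_u @ th, -np.inf, 30.0)
        mu = n_u * np.exp(eta)
        f = float(mu.sum() - s_u @ eta + th @ pen @ th)
        g = x_u.T @ (mu - s_u) + 2.0 * pen @ th
        return f, g, mu

    f, g, mu = objective(theta)
    damp = 0.0
    for it in range(max_iter):
        if np.max(np.abs(g)) < gtol:
            return theta, it
        h = (x_u * mu[:, None]).T @ x_u + 2.0 * pen
        if damp > 0:
            h = h + damp * np.eye(p)
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, g, rcond=None)[0]
        # scale-aware stop: further descent is below float precision of f
        if damp == 0 and (g @ step) / 2.0 < 1e-13 * (1.0 + abs(f)):
            return theta, it
        # backtracking line search (Armijo); on stall, damp the Hessian
        t = 1.0
        accepted = False
        for _ in range(40):
            f_new, g_new, mu_new = objective(theta - t * step)
            if f_new <= f - 1e-4 * t * (g @ step):
                theta = theta - t * step
                f, g, mu = f_new, g_new, mu_new
                accepted = True
                break
            t *= 0.5
        if accepted:
            damp = max(damp / 10.0, 0.0) if damp > 1e-10 else 0.0
        else:
            damp = 1e-6 * max(np.trace(h) / p, 1.0) if damp == 0 else damp * 100.0
            if damp > 1e12:  # pragma: no cover - pathological
                break
    if np.max(np.abs(g)) < 1e-3:  # loose fallback: usable but warn
        warnings.warn("Poisson GLM: gradient tolerance not fully reached")
        return theta, max_iter
    raise FitError(
        f"Newton did not converge: |grad|_inf = {np.max(np.abs(g)):.3g}"
    )


def _compress(
    design: DesignMatrix, y_inc: np.ndarray, subset: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sufficient statistics (X_u, n_u, s_u) for a frame subset."""
    cid = design.combo_id if subset is None else design.combo_id[subset]
    yy = y_inc if subset is None else y_inc[subset]
    u_all = len(design.combo_bins)
    n_u = np.bincount(cid, minlength=u_all)
    s_u = np.bincount(cid, weights=yy, minlength=u_all)
    present = n_u > 0
    x_u = design.onehot(design.combo_bins[present])
    return x_u, n_u[present].astype(float), s_u[present]


def fit_poisson_glm(
    design: DesignMatrix,
    y: np.ndarray,
    beta: float | dict[str, float],
    dt: float,
    subset: np.ndarray | None = None,
    lap: np.ndarray | None = None,
) -> GlmFit:
    """Single penalized ML fit on (a subset of) the included frames.

    ``y`` is the per-frame spike count over the full session frame base; the
    design's frame mask selects the modeled frames.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("spike counts must be nonnegative")
    y_inc = y[design.frame_index]
    if isinstance(beta, dict):
        beta_map = {v: float(beta[v]) for v in design.variables}
    else:
        beta_map = {v: float(beta) for v in design.variables}
    if any(b < 0 for b in beta_map.values()):
        raise ValueError("beta must be nonnegative")
    if lap is None:
        lap = grid_laplacian()
    pen = _penalty_matrix(design, beta_map, lap)
    x_u, n_u, s_u = _compress(design, y_inc, subset)
    theta, n_iter = _newton_poisson(x_u, n_u, s_u, pen)
    weights = {v: theta[design.block(v)].copy() for v in design.variables}
    return GlmFit(
        variables=design.variables,
        intercept=float(theta[0]),
        weights=weights,
        beta=beta_map,
        dt=dt,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


def make_folds(
    n_frames: int, n_folds: int = 10, chunk_frames: int = 600
) -> np.ndarray:
    """Fold label per included frame: contiguous ~10 s chunks dealt
    round-robin, so every fold mixes early and late session epochs while
    train/test frames stay separated at the chunk scale (spike trains are
    autocorrelated; frame-level interleaving would leak).
    """
    if n_frames < n_folds:
        raise ValueError("not enough frames for the requested folds")
    chunks = np.arange(n_frames) // max(1, chunk_frames)
    folds = chunks % n_folds
    if len(np.unique(folds)) < n_folds:
        # short session: fall back to equal contiguous blocks
        folds = (np.arange(n_frames) * n_folds) // n_frames
    return folds


def _test_llh_increase(
    fit_theta: np.ndarray,
    design: DesignMatrix,
    y_inc: np.ndarray,
    test: np.ndarray,
    mu_null: float,
) -> float:
    """Spike-normalized log-likelihood increase on a test fold, bits/spike."""
    x_u, n_u, s_u = _compress(design, y_inc, test)
    eta = x_u @ fit_theta
    ll_model = float(s_u @ eta - n_u @ np.exp(eta))
    n_test = n_u.sum()
    n_spk = s_u.sum()
    if n_spk == 0:
        return np.nan
    ll_null = float(n_spk * np.log(mu_null) - n_test * mu_null)
    return (ll_model - ll_null) / n_spk / LN2


def cross_validate(
    design: DesignMatrix,
    y: np.ndarray,
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID,
    n_folds: int = 10,
    folds: np.ndarray | None = None,
    dt: float = 1.0 / 60.0,
    lap: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Select the penalty on the grid by CV; return (best beta, fold values).

    The per-fold score is the held-out log-likelihood increase over a null
    model that predicts the training-mean rate, normalized by the number of
    held-out spikes (bits/spike).  Folds with zero held-out spikes are
    recorded as NaN and skipped in the mean (with a warning).
    """
    y = np.asarray(y)
    y_inc = y[design.frame_index]
    if folds is None:
        folds = make_folds(design.n_frames, n_folds)
    if lap is None:
        lap = grid_laplacian()
    uniq = np.unique(folds)
    results = np.full((len(beta_grid), len(uniq)), np.nan)
    for bi, beta in enumerate(beta_grid):
        pen = _penalty_matrix(design, {v: beta for v in design.variables}, lap)
        for fi, f in enumerate(uniq):
            test = folds == f
            train = ~test
            x_u, n_u, s_u = _compress(design, y_inc, train)
            theta, _ = _newton_poisson(x_u, n_u, s_u, pen)
            mu_null = max(float(y_inc[train].mean()), 1e-12)
            results[bi, fi] = _test_llh_increase(theta, design, y_inc, test, mu_null)
    if np.isnan(results).any():
        warnings.warn("some CV folds had zero held-out spikes; excluded")
    mean_scores = np.nanmean(results, axis=1)
    best = int(np.nanargmax(mean_scores))
    return float(beta_grid[best]), results[best]


# ---------------------------------------------------------------------------
# Forward model selection
# ---------------------------------------------------------------------------


@dataclass
class SelectionStep:
    variables: tuple[str, ...]
    beta: float
    fold_values: np.ndarray
    mean_value: float
    p_vs_previous: float | None
    accepted: bool


@dataclass
class TuningModel:
    neuron_id: int
    tuned: bool
    selected_variables: tuple[str, ...]
    fit: GlmFit | None
    selection_path: list[SelectionStep] = field(default_factory=list)
    p_vs_null: float | None = None

    @property
    def mean_cv_llh(self) -> float:
        if self.fit is None or self.fit.cv_llh_increase is None:
            return np.nan
        return float(np.nanmean(self.fit.cv_llh_increase))


def _wilcoxon_greater(values: np.ndarray, baseline: np.ndarray | float) -> float:
    """One-tailed exact signed-rank p for values > baseline across folds."""
    diff = np.asarray(values, float) - baseline
    diff = diff[~np.isnan(diff)]
    if len(diff) < 3 or np.allclose(diff, 0):
        return 1.0
    try:
        return float(
            stats.wilcoxon(diff, alternative="greater", method="exact").pvalue
        )
    except ValueError:
        return float(stats.wilcoxon(diff, alternative="greater").pvalue)


def select_model(
    bin_series: dict[str, BinSeries],
    y: np.ndarray,
    neuron_id: int = 0,
    candidates: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    beta_grid: tuple[float, ...] = DEFAULT_BETA_GRID,
    n_folds: int = 10,
    dt: float = 1.0 / 60.0,
) -> TuningModel:
    """Forward stepwise selection of a neuron's tuned-variable set.

    All candidate models share one frame base (frames where every candidate
    variable is defined) and one fold assignment, so fold values are paired
    across models.  A larger model is accepted only if its fold values beat
    the incumbent's in a one-tailed Wilcoxon signed-rank test at ``alpha``;
    the final model must additionally beat the mean-rate null.
    """
    if candidates is None:
        candidates = tuple(bin_series)
    if not candidates:
        raise ValueError("need at least one candidate variable")
    base = build_design_matrix([bin_series[v] for v in candidates])
    folds = make_folds(base.n_frames, n_folds)
    lap = grid_laplacian(bin_series[candidates[0]].grid.n_rows,
                         bin_series[candidates[0]].grid.n_cols)
    frame_base = base.frame_index

    def _design(vs: tuple[str, ...]) -> DesignMatrix:
        sub = [bin_series[v] for v in vs]
        d = build_design_matrix(sub)
        # restrict to the common frame base so folds pair across models
        keep = np.isin(d.frame_index, frame_base, assume_unique=True)
        bins = d.bin_idx[keep]
        combos, cid = np.unique(bins, axis=0, return_inverse=True)
        return DesignMatrix(
            variables=d.variables,
            n_bins=d.n_bins,
            frame_index=d.frame_index[keep],
            bin_idx=bins,
            combo_id=cid,
            combo_bins=combos,
        )

    def _evaluate(vs: tuple[str, ...]) -> tuple[DesignMatrix, float, np.ndarray]:
        d = _design(vs)
        beta, fold_vals = cross_validate(
            d, y, beta_grid=beta_grid, folds=folds, dt=dt, lap=lap
        )
        return d, beta, fold_vals

    path: list[SelectionStep] = []
    # step 1: all single-variable models; ties broken by candidate order
    singles = [_evaluate((v,)) for v in candidates]
    means = [float(np.nanmean(fv)) for _, _, fv in singles]
    best_i = int(np.argmax(means))
    current_vars = (candidates[best_i],)
    current_design, current_beta, current_folds = singles[best_i]
    for i, v in enumerate(candidates):
        path.append(
            SelectionStep((v,), singles[i][1], singles[i][2], means[i],
                          None, i == best_i)
        )

    # grow supersets of the incumbent
    remaining = [v for v in candidates if v not in current_vars]
    while remaining:
        trials = []
        for v in remaining:
            vs = current_vars + (v,)
            d, beta, fv = _evaluate(vs)
            p = _wilcoxon_greater(fv, current_folds)
            trials.append((vs, d, beta, fv, p))
        trials.sort(key=lambda t: -float(np.nanmean(t[3])))
        vs, d, beta, fv, p = trials[0]
        accepted = p < alpha
        path.append(SelectionStep(vs, beta, fv, float(np.nanmean(fv)), p, accepted))
        if not accepted:
            break
        current_vars, current_design, current_beta, current_folds = vs, d, beta, fv
        remaining = [v for v in candidates if v not in current_vars]

    p_null = _wilcoxon_greater(current_folds, 0.0)
    tuned = p_null < alpha
    fit = None
    if tuned:
        fit = fit_poisson_glm(current_design, y, current_beta, dt, lap=lap)
        fit.cv_llh_increase = current_folds
    return TuningModel(
        neuron_id=neuron_id,
        tuned=tuned,
        selected_variables=current_vars if tuned else (),
        fit=fit,
        selection_path=path,
        p_vs_null=p_null,
    )


def model_prediction_quality(
    fit: GlmFit,
    design: DesignMatrix,
    y: np.ndarray,
    smooth_sd_frames: float = 15.0,
) -> float:
    """Pearson r between temporally smoothed predicted and observed rates.

    Default smoothing SD is 15 frames (250 ms at 60 Hz).  Returns NaN when
    either smoothed series is constant.
    """
    pred = fit.rate_hz(design)
    obs = np.asarray(y)[design.frame_index] / fit.dt
    if smooth_sd_frames > 0:
        pred = ndimage.gaussian_filter1d(pred, smooth_sd_frames)
        obs = ndimage.gaussian_filter1d(obs.astype(float), smooth_sd_frames)
    if np.std(pred) < 1e-12 or np.std(obs) < 1e-12:
        return np.nan
    return float(np.corrcoef(pred, obs)[0, 1])
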