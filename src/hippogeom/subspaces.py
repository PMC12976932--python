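"""Population-subspace geometry across spatial variables.

All analyses start from z-scored population map matrices M_v (neurons x 36
bins).  Two covariance conventions are used, each matching its formula's
dimensions: neuron-space covariance ``C_v = M_v M_v' / (n_bins - 1)``
(N x N) for PCA / alignment / orthogonal-subspace work, and bin-space
covariance ``M_v' M_v / (N - 1)`` (36 x 36) for the half-split covariance
correlation.

The alignment index AI = tr(D_a' C_b D_a) / sum_i<=k sigma_b(i) measures the
fraction of variable b's variance lying in variable a's top-k principal
subspace, normalized by the best possible k-dimensional capture: 0 =
orthogonal subspaces, 1 = collinear.  Mutually orthogonal subspaces that
jointly capture maximal normalized variance are found by Riemannian
gradient ascent on the Stiefel manifold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Session
from .grid import Grid
from .maps import PopulationMatrix, zscore_rows


def _as_matrix(m: PopulationMatrix | np.ndarray) -> np.ndarray:
    return m.M if isinstance(m, PopulationMatrix) else np.asarray(m, float)


def neuron_covariance(m: PopulationMatrix | np.ndarray) -> np.ndarray:
    """N x N covariance of bin patterns (rows are already centered)."""
    x = _as_matrix(m)
    return x @ x.T / (x.shape[1] - 1)


def bin_covariance(m: PopulationMatrix | np.ndarray) -> np.ndarray:
    """n_bins x n_bins covariance across neurons."""
    x = _as_matrix(m)
    xc = x - x.mean(axis=0, keepdims=True)
    return xc.T @ xc / (x.shape[0] - 1)


def top_eigvectors(c: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(vectors N x k, eigenvalues k) of a symmetric PSD matrix, descending."""
    vals, vecs = np.linalg.eigh(c)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order], vals[order]


# ---------------------------------------------------------------------------
# PCA cross-variance and alignment index
# ---------------------------------------------------------------------------


@dataclass
class PcaCrossVariance:
    reference: str
    k: int
    var_explained_ref: float
    var_explained: dict[str, float]
    per_pc: dict[str, np.ndarray]  # per-PC captured variance fractions


def pca_cross_variance(
    m_ref: PopulationMatrix,
    others: list[PopulationMatrix],
    k: int = 10,
) -> PcaCrossVariance:
    """Fraction of each variable's variance captured by the reference's
    top-k principal components (neuron-space directions)."""
    x = _as_matrix(m_ref)
    n = x.shape[0]
    if n <= k:
        raise ValueError("need more neurons than components")
    c_ref = neuron_covariance(x)
    d, vals = top_eigvectors(c_ref, k)
    out: dict[str, float] = {}
    per_pc: dict[str, np.ndarray] = {}
    ref_total = float(np.trace(c_ref))
    for pm in others:
        c_o = neuron_covariance(pm)
        cap = np.array([d[:, j] @ c_o @ d[:, j] for j in range(k)])
        per_pc[pm.variable_id] = cap / np.trace(c_o)
        out[pm.variable_id] = float(cap.sum() / np.trace(c_o))
    return PcaCrossVariance(
        reference=m_ref.variable_id,
        k=k,
        var_explained_ref=float(vals.sum() / ref_total),
        var_explained=out,
        per_pc=per_pc,
    )


@dataclass
class AlignmentResult:
    pair: tuple[str, str]
    k: int
    ai: float
    null: np.ndarray | None
    p: float | None


def alignment_index_value(
    m_a: PopulationMatrix | np.ndarray,
    m_b: PopulationMatrix | np.ndarray,
    k: int = 10,
    basis: np.ndarray | None = None,
) -> float:
    """AI = tr(D_a' C_b D_a) / sum of top-k eigenvalues of C_b.

    ``basis`` overrides D_a (used for the random-subspace null).
    """
    c_b = neuron_covariance(m_b)
    if basis is None:
        c_a = neuron_covariance(m_a)
        basis, _ = top_eigvectors(c_a, k)
    _, vals_b = top_eigvectors(c_b, k)
    return float(np.trace(basis.T @ c_b @ basis) / vals_b.sum())


def alignment_index(
    m_a: PopulationMatrix | np.ndarray,
    m_b: PopulationMatrix | np.ndarray,
    k: int = 10,
    n_null: int = 1000,
    seed: int = 0,
    names: tuple[str, str] | None = None,
) -> AlignmentResult:
    """Alignment index with a covariance-matched random-subspace null.

    Null bases are built by drawing k vectors v_j = C_comb^(1/2) u_j (u_j
    standard normal, C_comb the covariance of the variable-concatenated
    data) and orthonormalizing; the one-sided p is the fraction of random
    subspaces whose AI is *smaller* than observed (small p = more orthogonal
    than chance).
    """
    xa, xb = _as_matrix(m_a), _as_matrix(m_b)
    if xa.shape[0] != xb.shape[0]:
        raise ValueError("matrices must share the neuron dimension")
    n = xa.shape[0]
    if n <= k:
        raise ValueError("need more neurons than subspace dimensions")
    ai = alignment_index_value(xa, xb, k=k)
    if names is None:
        names = (
            m_a.variable_id if isinstance(m_a, PopulationMatrix) else "a",
            m_b.variable_id if isinstance(m_b, PopulationMatrix) else "b",
        )
    if n_null == 0:
        return AlignmentResult(pair=names, k=k, ai=ai, null=None, p=None)
    c_comb = neuron_covariance(np.concatenate([xa, xb], axis=1))
    vals, vecs = np.linalg.eigh(c_comb)
    vals = np.clip(vals, 0.0, None)
    if np.sum(vals > 1e-12) < k:
        raise ValueError("combined covariance rank below k")
    root = vecs * np.sqrt(vals)
    rng = np.random.default_rng(seed)
    null = np.empty(n_null)
    for i in range(n_null):
        draws = root @ rng.standard_normal((n, k))
        q, _ = np.linalg.qr(draws)
        null[i] = alignment_index_value(xa, xb, k=k, basis=q)
    p = (np.sum(null < ai) + 1.0) / (n_null + 1.0)
    return AlignmentResult(pair=names, k=k, ai=ai, null=null, p=float(p))


# ---------------------------------------------------------------------------
# Half-split covariance correlation
# ---------------------------------------------------------------------------


def _split_population(
    session: Session,
    variables: tuple[str, str],
    rng: np.random.Generator,
    grid: Grid,
    smoothing_sd: float,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Raw map stacks for both variables from two disjoint trial halves."""
    from .maps import BinSeries, bin_position, stack_rate_maps

    ok = session.trials[session.trials["outcome"] == "captured"]
    order = rng.permutation(len(ok))
    half = len(ok) // 2
    halves = (order[:half], order[half : 2 * half])
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for v in set(variables):
        base = bin_position(session.trajectories[v], grid, None, None)
        stacks = []
        for sel in halves:
            mask = np.zeros(session.n_frames, dtype=bool)
            for _, row in ok.iloc[sel].iterrows():
                mask[int(row["start_frame"]) : int(row["end_frame"])] = True
            bins = BinSeries(v, np.where(mask, base.bins, -1), grid)
            raw, _ = stack_rate_maps(session.spikes, bins, smoothing_sd)
            stacks.append(raw)
        out[v] = (stacks[0], stacks[1])
    return out


def _offdiag_corr(c1: np.ndarray, c2: np.ndarray) -> float:
    iu = np.triu_indices(c1.shape[0], k=1)
    return float(np.corrcoef(c1[iu], c2[iu])[0, 1])


def covariance_split_correlation(
    session: Session,
    pair: tuple[str, str],
    n_iter: int = 500,
    seed: int = 0,
    grid: Grid | None = None,
    smoothing_sd: float = 0.5,
) -> tuple[float, float, float]:
    """Cross-variable vs within-variable covariance similarity.

    Per iteration the captured trials are split into two halves; the
    within-variable baseline correlates variable a's bin-space covariance
    between the halves (noise ceiling), the cross value correlates a's
    half-1 covariance with b's half-2 covariance over the same split, so
    both statistics face identical sampling noise.  Returns (mean cross r,
    mean within r, p) where p is the fraction of iterations with
    within > cross.  For a variable paired with itself cross and within
    coincide and ties are broken at random (p ~ 0.5).
    """
    if grid is None:
        grid = Grid(*session.field_size)
    if int((session.trials["outcome"] == "captured").sum()) < 4:
        raise ValueError("need >= 4 captured trials")
    rng = np.random.default_rng(seed)
    a, b = pair
    cross_vals = np.empty(n_iter)
    within_vals = np.empty(n_iter)
    wins = 0
    for i in range(n_iter):
        stacks = _split_population(session, pair, rng, grid, smoothing_sd)
        za1, _ = zscore_rows(stacks[a][0])
        za2, _ = zscore_rows(stacks[a][1])
        zb2, _ = zscore_rows(stacks[b][1])
        ca1 = bin_covariance(za1)
        ca2 = bin_covariance(za2)
        cb2 = bin_covariance(zb2)
        within_vals[i] = _offdiag_corr(ca1, ca2)
        cross_vals[i] = _offdiag_corr(ca1, cb2)
        if within_vals[i] > cross_vals[i]:
            wins += 1
        elif within_vals[i] == cross_vals[i] and rng.random() < 0.5:
            wins += 1
    return (
        float(cross_vals.mean()),
        float(within_vals.mean()),
        wins / n_iter,
    )


# ---------------------------------------------------------------------------
# Mutually orthogonal subspaces (Stiefel manifold)
# ---------------------------------------------------------------------------


@dataclass
class SubspaceBasis:
    variables: tuple[str, ...]
    bases: dict[str, np.ndarray]  # neuron x d_v, orthonormal, mutually orthogonal
    dims: dict[str, int]
    var_captured: dict[str, float]  # normalized by top-d_v eigenvalue sum
    objective: float
    objective_trace: np.ndarray
    n_starts_converged: int = 0


class OptimizationError(RuntimeError):
    pass


def _stiefel_ascent(
    c_list: list[np.ndarray],
    d_list: list[int],
    denom: np.ndarray,
    q0: np.ndarray,
    max_iter: int = 2000,
    gtol: float = 1e-6,
    ftol: float = 1e-9,
) -> tuple[np.ndarray, list[float]]:
    """Maximize sum_v tr(Q_v' C_v Q_v)/(V * denom_v) over joint Stiefel Q."""
    n, dtot = q0.shape
    v = len(c_list)
    offs = np.concatenate([[0], np.cumsum(d_list)])

    def value_grad(q: np.ndarray) -> tuple[float, np.ndarray]:
        f = 0.0
        g = np.zeros_like(q)
        for i, c in enumerate(c_list):
            qi = q[:, offs[i] : offs[i + 1]]
            cq = c @ qi
            f += np.trace(qi.T @ cq) / (v * denom[i])
            g[:, offs[i] : offs[i + 1]] = 2.0 * cq / (v * denom[i])
        return f, g

    def retract(q: np.ndarray) -> np.ndarray:
        qr_q, r = np.linalg.qr(q)
        return qr_q * np.sign(np.diag(r))

    q = q0
    f, g = value_grad(q)
    trace = [f]
    step = 1.0
    for _ in range(max_iter):
        # Riemannian gradient: project onto the Stiefel tangent space
        sym = (q.T @ g + g.T @ q) / 2.0
        rg = g - q @ sym
        gnorm = np.linalg.norm(rg)
        if gnorm < gtol:
            break
        improved = False
        while step > 1e-12:
            q_new = retract(q + step * rg)
            f_new, g_new = value_grad(q_new)
            if f_new > f + 1e-10 * step * gnorm**2:
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if abs(f_new - f) < ftol * max(abs(f), 1.0):
            q, f, g = q_new, f_new, g_new
            trace.append(f)
            break
        q, f, g = q_new, f_new, g_new
        trace.append(f)
        step = min(step * 2.0, 1e3)
    return q, trace


def optimize_orthogonal_subspaces(
    c_list: list[np.ndarray],
    d_list: list[int],
    variables: tuple[str, ...] | None = None,
    n_starts: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
) -> SubspaceBasis:
    """Jointly fit mutually orthogonal per-variable subspaces.

    Maximizes the equally weighted sum over variables of
    tr(Q_v' C_v Q_v) / sum_{i<=d_v} sigma_v(i) subject to the columns of all
    Q_v forming one orthonormal frame.  Multi-start (eigenvector-seeded plus
    random starts), best objective kept; the per-start objective trace is
    non-decreasing by construction of the line search.
    """
    nvar = len(c_list)
    if variables is None:
        variables = tuple(f"var{i}" for i in range(nvar))
    n = c_list[0].shape[0]
    if sum(d_list) > n:
        raise ValueError("total dimensionality exceeds neuron count")
    denom = np.empty(nvar)
    for i, (c, d) in enumerate(zip(c_list, d_list)):
        if not np.allclose(c, c.T, atol=1e-8):
            raise ValueError("covariance matrices must be symmetric")
        _, vals = top_eigvectors(c, d)
        denom[i] = vals.sum()
    dtot = sum(d_list)

    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = []
    # deterministic start: stacked top eigenvectors, jointly orthonormalized
    blocks = [top_eigvectors(c, d)[0] for c, d in zip(c_list, d_list)]
    q0, _ = np.linalg.qr(np.concatenate(blocks, axis=1))
    starts.append(q0[:, :dtot])
    for _ in range(n_starts - 1):
        q, _ = np.linalg.qr(rng.standard_normal((n, dtot)))
        starts.append(q)

    best: tuple[float, np.ndarray, list[float]] | None = None
    n_conv = 0
    for q0 in starts:
        q, trace = _stiefel_ascent(c_list, d_list, denom, q0, max_iter=max_iter)
        n_conv += 1
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], q, trace)
    if best is None:  # pragma: no cover
        raise OptimizationError("no start converged")
    _, q, trace = best
    offs = np.concatenate([[0], np.cumsum(d_list)])
    bases = {
        v: q[:, offs[i] : offs[i + 1]] for i, v in enumerate(variables)
    }
    captured = {
        v: float(np.trace(bases[v].T @ c_list[i] @ bases[v]) / denom[i])
        for i, v in enumerate(variables)
    }
    return SubspaceBasis(
        variables=variables,
        bases=bases,
        dims={v: d for v, d in zip(variables, d_list)},
        var_captured=captured,
        objective=trace[-1],
        objective_trace=np.array(trace),
        n_starts_converged=n_conv,
    )


def cross_projection_variance(
    matrices: dict[str, PopulationMatrix | np.ndarray],
    basis: SubspaceBasis,
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[dict[tuple[str, str], float], dict[tuple[str, str], float]]:
    """Fraction of each variable's variance in each fitted subspace.

    Bootstraps neurons (with replacement, projections recomputed on the
    resampled rows, bases fixed) and reports, for each cross pair, the
    fraction of bootstrap replicates in which the cross-subspace capture
    reaches the own-subspace capture — an upper-tail p for "the cross
    projection explains as much as the variable's own subspace".
    """
    rng = np.random.default_rng(seed)
    fractions: dict[tuple[str, str], float] = {}
    boots: dict[tuple[str, str], np.ndarray] = {}

    def frac(x: np.ndarray, q: np.ndarray) -> float:
        qo, _ = np.linalg.qr(q)  # re-orthonormalize (resampled basis rows)
        c = x @ x.T / (x.shape[1] - 1)
        return float(np.trace(qo.T @ c @ qo) / np.trace(c))

    mats = {v: _as_matrix(m) for v, m in matrices.items()}
    for v, x in mats.items():
        for u in basis.variables:
            fractions[(v, u)] = frac(x, basis.bases[u])
    n = next(iter(mats.values())).shape[0]
    idx_boot = [rng.integers(0, n, size=n) for _ in range(n_boot)]
    for v, x in mats.items():
        for u in basis.variables:
            if u == v:
                continue
            vals = np.empty(n_boot)
            for i, idx in enumerate(idx_boot):
                # resample neurons jointly in the maps and the basis rows
                xs = x[idx]
                vals[i] = frac(xs, basis.bases[u][idx]) - frac(
                    xs, basis.bases[v][idx]
                )
            boots[(v, u)] = vals
    p = {
        key: float((np.sum(vals >= 0) + 1.0) / (len(vals) + 1.0))
        for key, vals in boots.items()
    }
    return fractions, p


# ---------------------------------------------------------------------------
# Linear maps between subspace coordinates
# ---------------------------------------------------------------------------


@dataclass
class LinearMapResult:
    w: np.ndarray  # d_b x d_a
    r2_train: float
    r2_loocv: float
    null: np.ndarray | None
    p: float | None
    rank_deficient: bool = False


def _r2(x_b: np.ndarray, pred: np.ndarray) -> float:
    return 1.0 - np.linalg.norm(x_b - pred, "fro") ** 2 / np.linalg.norm(
        x_b, "fro"
    ) ** 2


def _ols(x_a: np.ndarray, x_b: np.ndarray) -> tuple[np.ndarray, bool]:
    w, _, rank, _ = np.linalg.lstsq(x_a.T, x_b.T, rcond=None)
    return w.T, rank < x_a.shape[0]


def _loocv_r2(x_a: np.ndarray, x_b: np.ndarray) -> float:
    c = x_a.shape[1]
    pred = np.empty_like(x_b)
    for j in range(c):
        keep = np.arange(c) != j
        w, _ = _ols(x_a[:, keep], x_b[:, keep])
        pred[:, j] = w @ x_a[:, j]
    return _r2(x_b, pred)


def fit_linear_map(
    x_a: np.ndarray,
    x_b: np.ndarray,
    n_shuffle: int = 1000,
    seed: int = 0,
) -> LinearMapResult:
    """Least-squares map W with X_b ~= W X_a over spatial-bin conditions.

    R^2 = 1 - ||X_b - W X_a||_F^2 / ||X_b||_F^2, on the full data and by
    leave-one-bin-out cross-validation.  The null permutes the entries
    within each row of X_a independently and refits; p is the fraction of
    shuffled LOOCV R^2 at least as large as observed (+1 correction).
    """
    x_a = np.asarray(x_a, float)
    x_b = np.asarray(x_b, float)
    if x_a.shape[1] != x_b.shape[1]:
        raise ValueError("condition counts differ")
    w, deficient = _ols(x_a, x_b)
    r2_train = _r2(x_b, w @ x_a)
    r2_loocv = _loocv_r2(x_a, x_b)
    if n_shuffle == 0:
        return LinearMapResult(w, float(r2_train), float(r2_loocv), None, None,
                               deficient)
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffle)
    c = x_a.shape[1]
    for i in range(n_shuffle):
        xs = np.stack([row[rng.permutation(c)] for row in x_a])
        null[i] = _loocv_r2(xs, x_b)
    p = (np.sum(null >= r2_loocv) + 1.0) / (n_shuffle + 1.0)
    return LinearMapResult(
        w=w,
        r2_train=float(r2_train),
        r2_loocv=float(r2_loocv),
        null=null,
        p=float(p),
        rank_deficient=deficient,
    )


def project_onto_basis(m: PopulationMatrix | np.ndarray, q: np.ndarray) -> np.ndarray:
    """Low-dimensional coordinates X = Q' M (d x n_bins)."""
    return q.T @ _as_matrix(m)
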