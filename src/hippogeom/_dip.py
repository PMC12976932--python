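"""Hartigan's dip statistic of unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex below the mode, concave above).  It is
computed by the classical iterative construction: fit the greatest convex
minorant (GCM) and least concave majorant (LCM) of the empirical CDF on a
shrinking candidate modal interval, accumulate the one-sided deviations
outside that interval, and stop when the GCM-LCM gap no longer exceeds the
accumulated deviation.  All intermediate quantities are kept in count units
over the sorted sample (tied values appear as vertical hull segments); the
returned statistic is ``accumulated / (2 n)``.

The dip is bounded below by ``1 / (2 n)`` (attained by perfectly uniform
spacing) and above by ``1/4`` (two equal point masses).
"""

from __future__ import annotations

import numpy as np


def _gcm_vertices(x: np.ndarray, low: int, high: int) -> np.ndarray:
    """Indices of the greatest-convex-minorant touch points of (x[j], j)
    on [low, high]; tied abscissae stay as vertical segments."""
    hull: list[int] = [low]
    for j in range(low + 1, high + 1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            # pop b unless the turn a->b->j is strictly convex
            if (x[j] - x[b]) * (b - a) < (x[b] - x[a]) * (j - b):
                break
            hull.pop()
        hull.append(j)
    return np.array(hull)


def _lcm_vertices(x: np.ndarray, low: int, high: int) -> np.ndarray:
    """Least-concave-majorant touch points of (x[j], j) on [low, high]."""
    hull: list[int] = [low]
    for j in range(low + 1, high + 1):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            if (x[j] - x[b]) * (b - a) > (x[b] - x[a]) * (j - b):
                break
            hull.pop()
        hull.append(j)
    return np.array(hull)


def _line_at(x: np.ndarray, a: int, b: int, xq: float, vertical: float) -> float:
    """Value at xq of the segment joining (x[a], a) and (x[b], b)."""
    if x[b] == x[a]:
        return vertical
    return a + (xq - x[a]) * (b - a) / (x[b] - x[a])


def dip_statistic(samples: np.ndarray) -> float:
    """Dip statistic of a 1-D sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2 or x[0] == x[-1]:
        return 0.0

    low, high = 0, n - 1
    dip = 1.0  # count units; 1/(2n) after final scaling
    for _ in range(n):  # the modal interval strictly shrinks; n is a safe cap
        gcm = _gcm_vertices(x, low, high)  # ascending index order
        lcm = _lcm_vertices(x, low, high)

        # largest gap between the LCM and GCM curves, bracketing vertices
        d = 1.0
        new_low, new_high = low, high
        for v in lcm:
            k = int(np.searchsorted(gcm, v, side="right")) - 1
            g1 = int(gcm[max(k, 0)])
            g2 = int(gcm[min(k + 1, len(gcm) - 1)])
            dx = (v + 1) - _line_at(x, g1, g2, x[v], vertical=g1)
            if dx > d:
                d, new_low, new_high = dx, g1, int(v)
        for g in gcm:
            k = int(np.searchsorted(lcm, g, side="left"))
            l2 = int(lcm[min(k, len(lcm) - 1)])
            l1 = int(lcm[max(k - 1, 0)])
            dx = _line_at(x, l1, l2, x[g], vertical=l2) - (g - 1)
            if dx > d:
                d, new_low, new_high = dx, int(g), l2
        if d <= dip:
            break

        # one-sided ECDF deviations outside the new modal interval
        dip_l = 1.0
        for a, b in zip(gcm[:-1], gcm[1:]):
            if b <= new_low and b - a > 1 and x[b] != x[a]:
                slope = (b - a) / (x[b] - x[a])
                jj = np.arange(a, b + 1)
                t = (jj - a + 1) - (x[jj] - x[a]) * slope
                dip_l = max(dip_l, float(t.max()))
        dip_u = 1.0
        for a, b in zip(lcm[:-1], lcm[1:]):
            if a >= new_high and b - a > 1 and x[b] != x[a]:
                slope = (b - a) / (x[b] - x[a])
                jj = np.arange(a, b + 1)
                t = (x[jj] - x[a]) * slope - (jj - a - 1)
                dip_u = max(dip_u, float(t.max()))
        dip = max(dip, dip_l, dip_u)
        if (new_low, new_high) == (low, high):
            break
        low, high = new_low, new_high

    return dip / (2.0 * n)


def dip_test(
    samples: np.ndarray, n_boot: int = 2000, seed: int | None = 0
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against a uniform null.

    The null distribution is the dip of ``n_boot`` uniform samples of the
    same size (the classical calibration); p is the fraction of bootstrap
    dips at least as large as the observed one, with a +1 correction.
    """
    samples = np.asarray(samples, dtype=float)
    stat = dip_statistic(samples)
    rng = np.random.default_rng(seed)
    n = len(samples)
    null = np.array(
        [dip_statistic(rng.random(n)) for _ in range(n_boot)]
    )
    p = (np.sum(null >= stat) + 1.0) / (n_boot + 1.0)
    return stat, float(p)
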