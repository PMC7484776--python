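"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the code paths they check: the circle oracle is
a grid search over geometric least squares, the KS oracle enumerates the
empirical-CDF step points, and the ANOVA oracle is the textbook
sum-of-squares arithmetic.
"""
from __future__ import annotations

import cmath

import numpy as np


def cole_point(r0: float, r_inf: float, alpha: float, fc: float, f: float) -> complex:
    """Cole impedance via python complex arithmetic (no numpy broadcasting)."""
    return r_inf + (r0 - r_inf) / (1 + (1j * f / fc) ** alpha)


def grid_circle_fit(points, n_grid: int = 21, n_refine: int = 6):
    """Geometric least-squares circle by iterated grid search.

    Minimizes sum_i (|p_i - c| - r)^2 over a shrinking grid around the
    centroid; radius is profiled out analytically (optimal r is the mean
    distance), so the search is 2-D.
    """
    pts = np.asarray(points, dtype=float)

    def cost(cx, cy):
        d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
        return np.sum((d - d.mean()) ** 2)

    cx0, cy0 = pts.mean(axis=0)
    spread = 3.0 * max(pts[:, 0].std(), pts[:, 1].std(), 1e-6)
    best = (cx0, cy0)
    for _ in range(n_refine):
        xs = np.linspace(best[0] - spread, best[0] + spread, n_grid)
        ys = np.linspace(best[1] - spread, best[1] + spread, n_grid)
        costs = np.array([[cost(x, y) for x in xs] for y in ys])
        iy, ix = np.unravel_index(np.argmin(costs), costs.shape)
        best = (xs[ix], ys[iy])
        spread *= 2.5 / (n_grid - 1)  # zoom in around the incumbent
    d = np.hypot(pts[:, 0] - best[0], pts[:, 1] - best[1])
    return best[0], best[1], float(d.mean())


def ks_statistic_enumerated(x, mean: float, sd: float) -> float:
    """One-sample KS statistic against N(mean, sd) by step enumeration."""
    from scipy.stats import norm

    xs = np.sort(np.asarray(x, dtype=float))
    n = xs.size
    d = 0.0
    for i, v in enumerate(xs, start=1):
        cdf = norm.cdf(v, loc=mean, scale=sd)
        d = max(d, abs(cdf - i / n), abs(cdf - (i - 1) / n))
    return d


def anova_f_hand(groups) -> float:
    """Textbook one-way ANOVA F: (SSB/(k-1)) / (SSW/(N-k))."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    grand = np.concatenate(gs).mean()
    n_total = sum(g.size for g in gs)
    k = len(gs)
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(np.sum((g - g.mean()) ** 2) for g in gs)
    return (ssb / (k - 1)) / (ssw / (n_total - k))


def dunn_z_hand(a, b) -> float:
    """Two-group Dunn z from first principles (no ties assumed)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    values = np.concatenate([a, b])
    order = np.argsort(values)
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, values.size + 1)
    ra = ranks[: a.size].mean()
    rb = ranks[a.size :].mean()
    n = values.size
    se = np.sqrt(n * (n + 1) / 12.0 * (1.0 / a.size + 1.0 / b.size))
    return (ra - rb) / se
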