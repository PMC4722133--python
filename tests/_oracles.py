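"""Independent oracles for cross-checking the fitting pipeline.

Deliberately separate numerical route from the package: the linear
subproblem is solved by closed-form 2x2 normal equations (the package
uses lstsq) and the 1-D search is a dense log-spaced grid followed by
golden-section refinement (the package uses a multistart plus bounded
Brent).
"""

from __future__ import annotations

import math

import numpy as np

GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def normal_eq_sse(family: str, b: float, t: np.ndarray, y: np.ndarray) -> float:
    """SSE of the best (A, C) at fixed b via closed-form normal equations."""
    g = np.exp(-b * t) if family == "exponential" else t ** (-b)
    n = t.size
    Sg, Sy = g.sum(), y.sum()
    Sgg, Sgy = (g * g).sum(), (g * y).sum()
    det = n * Sgg - Sg * Sg
    if det <= 0:
        # basis collinear with the intercept: best fit is the mean
        r = y - y.mean()
        return float(r @ r)
    A = (n * Sgy - Sg * Sy) / det
    C = (Sy * Sgg - Sg * Sgy) / det
    r = y - A * g - C
    return float(r @ r)


def grid_oracle_sse(
    family: str,
    t: np.ndarray,
    y: np.ndarray,
    b_range: tuple[float, float],
    n_grid: int = 2000,
    refine_iters: int = 120,
) -> float:
    """Global minimum SSE over b by exhaustive grid + golden-section polish."""
    grid = np.geomspace(b_range[0], b_range[1], n_grid)
    sse = np.array([normal_eq_sse(family, b, t, y) for b in grid])
    i = int(np.argmin(sse))
    lo = math.log(grid[max(i - 1, 0)])
    hi = math.log(grid[min(i + 1, n_grid - 1)])
    f = lambda u: normal_eq_sse(family, math.exp(u), t, y)  # noqa: E731
    a, b_ = lo, hi
    c = b_ - GOLDEN * (b_ - a)
    d = a + GOLDEN * (b_ - a)
    fc, fd = f(c), f(d)
    for _ in range(refine_iters):
        if fc < fd:
            b_, d, fd = d, c, fc
            c = b_ - GOLDEN * (b_ - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + GOLDEN * (b_ - a)
            fd = f(d)
    return float(min(sse[i], fc, fd))
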