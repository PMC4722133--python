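"""Unweighted least-squares fitting of decay curves to SVH setting series.

Both candidate families are *separable*: for a fixed decay rate ``b`` the
model is linear in (A, C), so the three-parameter fit reduces to a
one-dimensional global search over ``b`` (variable projection).  The
search is a deterministic multistart: the profiled SSE(b) is evaluated on
a log-spaced grid, every local minimum on the grid is refined by bounded
scalar minimization in log-b, and the best refined optimum is kept.  Each
datum receives equal weight; (A, C) are unconstrained.

Run-level fits are averaged into individual-level summaries before any
group statistics (two-run subjects contribute the arithmetic mean of
their run parameters, extremes and RMS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .decay_models import (
    DecayParams,
    Family,
    ObservationInterval,
    eval_model,
    interval_extremes,
    time_constant,
)

__all__ = [
    "SettingSeries",
    "MultistartConfig",
    "FitResult",
    "IndividualSummary",
    "sse",
    "fit_series",
    "fit_points",
    "fit_cohort",
    "average_runs",
    "summarize_individuals",
]


@dataclass(frozen=True)
class SettingSeries:
    """One centrifuge run: ordered (time, SVH) line settings.

    Times are seconds since the beginning of the G plateau and must be
    strictly increasing and positive; SVH is in degrees, right tilt
    positive.  ``g_level`` is metadata (multiples of Earth gravity).
    """

    subject_id: str
    run_id: int
    times: np.ndarray
    svh: np.ndarray
    g_level: float = 2.5

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.svh, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "svh", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("times and svh must be 1-D arrays of equal length")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError(f"non-finite time in series {self.subject_id}/{self.run_id}")
        if t.size and np.any(t <= 0):
            raise ValueError(
                f"all times must be > 0 (series {self.subject_id}/{self.run_id})"
            )
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError(
                f"times must be strictly increasing (series {self.subject_id}/{self.run_id})"
            )

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class MultistartConfig:
    """Deterministic multistart for the 1-D profiled search over b.

    ``n_starts`` log-spaced grid points span ``b_range_exponential`` or
    ``b_range_power`` (s^-1 for the exponential family; dimensionless for
    the power family).  Refinement stops at ``rel_tol`` relative SSE
    change; among candidates within ``tie_tol`` relative SSE of the best,
    the smallest b (flattest curve) is reported.
    """

    n_starts: int = 64
    b_range_exponential: tuple[float, float] = (1e-4, 2.0)
    b_range_power: tuple[float, float] = (1e-4, 4.0)
    rel_tol: float = 1e-10
    tie_tol: float = 1e-9

    def b_range(self, family: Family) -> tuple[float, float]:
        if family is Family.POWER:
            return self.b_range_power
        return self.b_range_exponential

    def grid(self, family: Family) -> np.ndarray:
        lo, hi = self.b_range(family)
        return np.geomspace(lo, hi, self.n_starts)


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one family to one run."""

    subject_id: str
    run_id: int
    params: DecayParams
    sse: float
    rms: float
    n: int
    f_tmin: float
    f_tmax: float
    converged: bool
    n_starts_used: int


@dataclass(frozen=True)
class IndividualSummary:
    """Run-averaged parameters, extremes and RMS for one subject.

    For single-run subjects the summary equals the run's values.  The
    time constant ``T`` (seconds) is 1/(run-averaged b), exponential
    family only.
    """

    subject_id: str
    family: Family
    A: float
    b: float
    C: float
    f_tmin: float
    f_tmax: float
    rms: float
    n_runs: int
    T: float | None = None


def sse(params: DecayParams, series: SettingSeries) -> float:
    """Equal-weight sum of squared residuals of the model over the series."""
    resid = series.svh - eval_model(params, series.times)
    return float(np.dot(resid, resid))


def _basis(family: Family, b: float, t: np.ndarray) -> np.ndarray:
    if family is Family.POWER:
        return t ** (-b)
    return np.exp(-b * t)


def _linear_subproblem(
    family: Family, b: float, t: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """Exact unconstrained least-squares (A, C) at fixed b; returns (A, C, sse)."""
    g = _basis(family, b, t)
    X = np.column_stack([g, np.ones_like(g)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(np.dot(resid, resid))


_GOLDEN = 0.6180339887498949


def _golden_polish(
    f, center: float, lo: float, hi: float, half_width: float = 1e-6, iters: int = 60
):
    """Golden-section shrink of a narrow bracket around ``center``,
    returning the best (x, f(x)) evaluated."""
    a = max(lo, center - half_width)
    b = min(hi, center + half_width)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc <= fd else (d, fd)
    for _ in range(iters):
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
            if fc < best_f:
                best_x, best_f = c, fc
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
            if fd < best_f:
                best_x, best_f = d, fd
    return best_x, best_f


def _profiled_sse(family: Family, t: np.ndarray, y: np.ndarray):
    def f(log_b: float) -> float:
        return _linear_subproblem(family, float(np.exp(log_b)), t, y)[2]

    return f


def fit_series(
    series: SettingSeries,
    family: Family | str,
    starts: MultistartConfig | None = None,
    interval: ObservationInterval | None = None,
) -> FitResult:
    """Fit one decay family to one setting series by global least squares.

    Deterministic given the multistart configuration.  Raises for series
    with fewer than 4 settings (three parameters need n > p) or with
    non-finite observations.
    """
    return fit_points(
        series.times,
        series.svh,
        family,
        starts=starts,
        interval=interval,
        subject_id=series.subject_id,
        run_id=series.run_id,
    )


def fit_points(
    times,
    svh,
    family: Family | str,
    starts: MultistartConfig | None = None,
    interval: ObservationInterval | None = None,
    subject_id: str = "<points>",
    run_id: int = 0,
) -> FitResult:
    """Point-level fit entry used for both single runs and pooled data.

    Unlike :class:`SettingSeries`, tied time values are permitted here —
    pooling all settings from many runs legitimately produces coincident
    times.  Times must still be positive (power-family domain).
    """
    family = Family(family)
    if family is Family.WICKELGREN:
        raise ValueError("fitting is supported for the exponential and power families")
    starts = starts or MultistartConfig()
    interval = interval or ObservationInterval()
    t = np.asarray(times, dtype=float)
    y = np.asarray(svh, dtype=float)
    n = int(t.size)
    if n < 4:
        raise ValueError(f"need at least 4 settings for a 3-parameter fit, got {n}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError(f"non-finite observation in series {subject_id}/{run_id}")
    if np.any(t <= 0):
        raise ValueError("all times must be > 0")

    grid = starts.grid(family)
    sse_grid = np.array([_linear_subproblem(family, b, t, y)[2] for b in grid])

    # Constant series: SSE(b) is flat and b is unidentified; report the
    # A -> 0 solution with C = mean(svh) at the smallest b (tie-break rule)
    # rather than chasing the b -> inf ridge.
    scale = max(float(np.max(sse_grid)), float(np.dot(y, y)), 1.0)
    if float(np.max(sse_grid) - np.min(sse_grid)) <= starts.rel_tol * scale:
        c0 = float(np.mean(y))
        params = DecayParams(family=family, A=0.0, b=grid[0], C=c0)
        resid = y - c0
        s = float(np.dot(resid, resid))
        lo, hi = interval_extremes(params, interval)
        return FitResult(
            subject_id=subject_id,
            run_id=run_id,
            params=params,
            sse=s,
            rms=float(np.sqrt(s / n)),
            n=n,
            f_tmin=lo,
            f_tmax=hi,
            converged=True,
            n_starts_used=starts.n_starts,
        )

    # Refine every grid-local minimum by bounded minimization in log-b.
    obj = _profiled_sse(family, t, y)
    log_grid = np.log(grid)
    candidates: list[tuple[float, float]] = []  # (sse, b)
    converged = True
    for i in range(len(grid)):
        left = sse_grid[i - 1] if i > 0 else np.inf
        right = sse_grid[i + 1] if i < len(grid) - 1 else np.inf
        if sse_grid[i] <= left and sse_grid[i] <= right:
            lo = log_grid[max(i - 1, 0)]
            hi = log_grid[min(i + 1, len(grid) - 1)]
            if lo == hi:
                candidates.append((float(sse_grid[i]), float(grid[i])))
                continue
            res = minimize_scalar(
                obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
            )
            converged &= bool(res.success)
            # Brent's scaled tolerance floors at ~sqrt(eps)*|x|; a fixed
            # golden-section polish around its answer recovers the last
            # digits of b (tracking the best point seen is noise-robust).
            u_best, f_best = _golden_polish(obj, float(res.x), lo, hi)
            if f_best < res.fun:
                candidates.append((f_best, float(np.exp(u_best))))
            candidates.append((float(res.fun), float(np.exp(res.x))))
            candidates.append((float(sse_grid[i]), float(grid[i])))

    best_sse = min(s for s, _ in candidates)
    # Tie-break: smallest b among candidates within tie_tol relative SSE.
    tol = starts.tie_tol * max(best_sse, np.finfo(float).tiny)
    b_star = min(b for s, b in candidates if s - best_sse <= tol)
    A, C, s_star = _linear_subproblem(family, b_star, t, y)
    params = DecayParams(family=family, A=A, b=b_star, C=C)
    lo_v, hi_v = interval_extremes(params, interval)
    return FitResult(
        subject_id=subject_id,
        run_id=run_id,
        params=params,
        sse=s_star,
        rms=float(np.sqrt(s_star / n)),
        n=n,
        f_tmin=lo_v,
        f_tmax=hi_v,
        converged=converged,
        n_starts_used=starts.n_starts,
    )


def average_runs(results: list[FitResult]) -> IndividualSummary:
    """Arithmetic mean of run-level parameters, extremes and RMS for one subject.

    Accepts 1 or 2 results for the same subject and family.  The time
    constant is computed from the run-averaged b (exponential family).
    """
    if not 1 <= len(results) <= 2:
        raise ValueError(f"expected 1 or 2 run results, got {len(results)}")
    subjects = {r.subject_id for r in results}
    families = {r.params.family for r in results}
    if len(subjects) != 1:
        raise ValueError(f"results mix subjects: {sorted(subjects)}")
    if len(families) != 1:
        raise ValueError(f"results mix families: {sorted(f.value for f in families)}")
    family = results[0].params.family
    mean = lambda xs: float(np.mean(xs))  # noqa: E731
    b_bar = mean([r.params.b for r in results])
    return IndividualSummary(
        subject_id=results[0].subject_id,
        family=family,
        A=mean([r.params.A for r in results]),
        b=b_bar,
        C=mean([r.params.C for r in results]),
        f_tmin=mean([r.f_tmin for r in results]),
        f_tmax=mean([r.f_tmax for r in results]),
        rms=mean([r.rms for r in results]),
        n_runs=len(results),
        T=time_constant(b_bar) if family is Family.EXPONENTIAL else None,
    )


def fit_cohort(
    all_series: list[SettingSeries],
    family: Family | str,
    starts: MultistartConfig | None = None,
    interval: ObservationInterval | None = None,
) -> list[FitResult]:
    """Fit every run in a cohort; convenience wrapper over :func:`fit_series`."""
    return [fit_series(s, family, starts, interval) for s in all_series]


def summarize_individuals(results: list[FitResult]) -> list[IndividualSummary]:
    """Group run-level results by subject (insertion order) and run-average."""
    by_subject: dict[str, list[FitResult]] = {}
    for r in results:
        by_subject.setdefault(r.subject_id, []).append(r)
    return [average_runs(rs) for rs in by_subject.values()]
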