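"""Synthetic SVH cohorts and centrifuge stimulus kinematics.

The original raw setting series were never deposited, so study-conformant
cohorts are generated here: each run follows ``SVH(t) = A exp(-b t) + C``
with independent Gaussian setting noise, parameters drawn from
distributions whose means and SDs match the published group statistics,
and setting times drawn from the protocol schedule (3-5 settings per
minute over a 6-minute plateau, none before 4 s).

Defaults encode the study conditions: 27 subjects, 17 of them with two
runs; amplitude A ~ lognormal(mean 27.8 deg, SD 15.2 deg); decay rate
b ~ lognormal(mean 0.018 /s, SD 0.0147 /s) — the large coefficient of
variation of b is what drives the averaging artifact; asymptote
C ~ normal(0.5 deg, 6.1 deg); per-run setting-noise SD ~ lognormal(mean
2.4 deg, SD 1.0 deg) with a 0.3 deg floor.  A and b are positive by
construction.  Two-run subjects share a subject-level component with
intra-subject correlation 0.7 (a modeling choice, not a study estimate).

The module also provides a multi-trace generator (a sum of exponentials
with different time constants — the mechanism by which a single
individual could exhibit power-law forgetting) and the stimulus
kinematics of a swing-out gondola centrifuge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decay_models import Family
from .fitting import (
    FitResult,
    MultistartConfig,
    SettingSeries,
    fit_cohort,
    summarize_individuals,
)
from .group_analysis import PooledFit, pool_all_points, pool_binned

__all__ = [
    "CohortConfig",
    "CentrifugeProfile",
    "Kinematics",
    "sample_cohort",
    "multi_trace_series",
    "centrifuge_kinematics",
    "aggregation_experiment",
    "AggregationReport",
]

STANDARD_GRAVITY = 9.81  # m/s^2


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Lognormal (mu, sigma) with the given arithmetic mean and SD."""
    if mean <= 0 or sd <= 0:
        raise ValueError("lognormal moments require mean > 0 and sd > 0")
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


@dataclass(frozen=True)
class CohortConfig:
    """Distributions, schedule and seed governing cohort generation.

    Moments are arithmetic mean/SD of the sampled quantity (degrees for
    A and C, s^-1 for b, degrees for the setting-noise SD).  The setting
    schedule draws the first setting uniformly in ``first_setting`` and
    inter-setting gaps uniformly in ``gap`` seconds, out to ``t_end``.
    """

    n_subjects: int = 27
    n_two_run: int = 17
    A_mean: float = 27.8
    A_sd: float = 15.2
    b_mean: float = 0.018
    b_sd: float = 0.0147
    C_mean: float = 0.5
    C_sd: float = 6.1
    noise_mean: float = 2.4
    noise_sd: float = 1.0
    noise_floor: float = 0.3
    first_setting: tuple[float, float] = (4.0, 20.0)
    gap: tuple[float, float] = (12.0, 20.0)
    t_end: float = 360.0
    run_correlation: float = 0.7
    g_level: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or not 0 <= self.n_two_run <= self.n_subjects:
            raise ValueError("need 0 <= n_two_run <= n_subjects, n_subjects >= 1")
        for name in ("A", "b"):
            if getattr(self, f"{name}_mean") <= 0 or getattr(self, f"{name}_sd") <= 0:
                raise ValueError(f"{name} distribution requires positive mean and SD")
        if self.noise_mean <= 0 or self.noise_sd <= 0 or self.noise_floor < 0:
            raise ValueError("invalid noise distribution")
        if not 0 <= self.run_correlation <= 1:
            raise ValueError("run_correlation must lie in [0, 1]")
        if not 0 < self.first_setting[0] <= self.first_setting[1]:
            raise ValueError("invalid first-setting window")
        if not 0 < self.gap[0] <= self.gap[1]:
            raise ValueError("invalid inter-setting gap range")


def _schedule(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    times = [rng.uniform(*config.first_setting)]
    while True:
        nxt = times[-1] + rng.uniform(*config.gap)
        if nxt > config.t_end:
            break
        times.append(nxt)
    return np.asarray(times)


def _correlated_z(
    rng: np.random.Generator, z_subject: float, rho: float
) -> float:
    return math.sqrt(rho) * z_subject + math.sqrt(1.0 - rho) * rng.standard_normal()


def sample_cohort(
    config: CohortConfig,
) -> tuple[list[SettingSeries], pd.DataFrame]:
    """Draw a synthetic cohort; returns (series, generating truth).

    Every run follows an exponential decay exactly, plus i.i.d. Gaussian
    setting noise.  The truth frame carries the generating (A, b, C) and
    noise SD per run for parameter-recovery experiments.  Reproducible:
    the same config (including seed) yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    muA, sigA = _lognormal_mu_sigma(config.A_mean, config.A_sd)
    mub, sigb = _lognormal_mu_sigma(config.b_mean, config.b_sd)
    mun, sign = _lognormal_mu_sigma(config.noise_mean, config.noise_sd)
    rho = config.run_correlation

    series: list[SettingSeries] = []
    truth_rows = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        n_runs = 2 if i < config.n_two_run else 1
        zA_s, zb_s, zC_s = rng.standard_normal(3)
        for run in range(1, n_runs + 1):
            A = math.exp(muA + sigA * _correlated_z(rng, zA_s, rho))
            b = math.exp(mub + sigb * _correlated_z(rng, zb_s, rho))
            C = config.C_mean + config.C_sd * _correlated_z(rng, zC_s, rho)
            noise = max(math.exp(mun + sign * rng.standard_normal()), config.noise_floor)
            t = _schedule(rng, config)
            y = A * np.exp(-b * t) + C + rng.normal(0.0, noise, size=t.size)
            series.append(
                SettingSeries(
                    subject_id=subject,
                    run_id=run,
                    times=t,
                    svh=y,
                    g_level=config.g_level,
                )
            )
            truth_rows.append((subject, run, A, b, C, noise, t.size))
    truth = pd.DataFrame(
        truth_rows, columns=["subject", "run", "A", "b", "C", "noise_sd", "n"]
    )
    return series, truth


def multi_trace_series(
    weights,
    rates,
    times=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    subject_id: str = "MT",
    run_id: int = 1,
    config: CohortConfig | None = None,
) -> SettingSeries:
    """A series whose decay is a sum of exponential memory traces.

    ``svh(t) = sum_i w_i exp(-r_i t) + noise``.  With several traces whose
    rates span decades, the compound decay within one individual can be
    better fit by a power function even though every trace is exponential.
    ``times`` may be given explicitly; otherwise the protocol schedule is
    drawn from ``config`` (defaults) with the given seed.
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(rates, dtype=float)
    if w.shape != r.shape or w.ndim != 1:
        raise ValueError("weights and rates must be 1-D arrays of equal length")
    if w.size < 1:
        raise ValueError("need at least one trace")
    if np.any(w < 0):
        raise ValueError("trace weights must be >= 0")
    if np.any(r <= 0):
        raise ValueError("trace decay rates must be > 0")
    rng = np.random.default_rng(seed)
    if times is None:
        times = _schedule(rng, config or CohortConfig())
    t = np.asarray(times, dtype=float)
    y = np.exp(-np.outer(t, r)) @ w
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.size)
    return SettingSeries(subject_id=subject_id, run_id=run_id, times=t, svh=y)


@dataclass(frozen=True)
class CentrifugeProfile:
    """Geometry and drive of a swing-out gondola centrifuge."""

    radius: float = 7.25  # m
    angular_acceleration: float = 15.0  # deg/s^2 (15 or 7 in the protocol)
    target_g: float = 2.5  # resultant, multiples of Earth gravity
    gravity: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.target_g < 1:
            raise ValueError(
                "resultant G cannot be below 1 (gravity alone) for a ground "
                "centrifuge"
            )
        if self.angular_acceleration <= 0:
            raise ValueError("angular acceleration must be positive")


@dataclass(frozen=True)
class Kinematics:
    """Steady-state stimulus kinematics at the target G level."""

    omega_deg_s: float  # centrifuge angular velocity about the main axle
    tilt_deg: float  # gondola roll inclination (alignment with the resultant)
    ramp_time_s: float  # time to spin up to omega at constant acceleration
    g_level: float  # resultant recomputed from omega and radius (self-check)


def centrifuge_kinematics(profile: CentrifugeProfile) -> Kinematics:
    """Angular velocity, gondola swing-out angle and ramp time for a profile.

    At constant rotation the centripetal acceleration is a = omega^2 * r,
    so the resultant is G = sqrt(1 + (a/g)^2) and the freely swinging
    gondola aligns with it at tilt = atan(a/g) from Earth-horizontal.
    Solving for the target G: a/g = sqrt(G^2 - 1).
    """
    a_over_g = math.sqrt(profile.target_g**2 - 1.0)
    tilt = math.degrees(math.atan(a_over_g))
    a = a_over_g * profile.gravity
    omega_rad = math.sqrt(a / profile.radius)
    omega = math.degrees(omega_rad)
    ramp = omega / profile.angular_acceleration
    g_check = math.sqrt(1.0 + (omega_rad**2 * profile.radius / profile.gravity) ** 2)
    return Kinematics(
        omega_deg_s=omega, tilt_deg=tilt, ramp_time_s=ramp, g_level=g_check
    )


@dataclass(frozen=True)
class AggregationReport:
    """Outcome of the averaging-artifact experiment on one synthetic cohort.

    Pooling heterogeneous exponential decays erodes the exponential
    family's per-individual RMS advantage: the all-points gap ratio is
    expected to sit much closer to 1 than the mean per-individual ratio.
    """

    truth: pd.DataFrame
    exp_results: list[FitResult]
    pow_results: list[FitResult]
    n_runs: int
    n_exponential_wins: int
    win_fraction: float
    mean_individual_gap_ratio: float
    binned: dict[int, PooledFit]
    all_points: PooledFit

    @property
    def all_points_gap_ratio(self) -> float:
        return self.all_points.rms_gap_ratio

    def gap_ratios(self) -> dict[str, float]:
        out = {f"binned_{k}": pf.rms_gap_ratio for k, pf in self.binned.items()}
        out["all_points"] = self.all_points_gap_ratio
        out["mean_individual"] = self.mean_individual_gap_ratio
        return out


def aggregation_experiment(
    config: CohortConfig,
    k_bins_list: tuple[int, ...] = (15, 5),
    starts: MultistartConfig | None = None,
) -> AggregationReport:
    """Generate a cohort, fit per run, pool three ways, compare families.

    Fully reproducible given ``config.seed``.  Reports the per-run
    exponential win count, the mean per-individual power/exponential RMS
    ratio (run-averaged per subject first), the binned pooled fits for
    each requested bin count, and the all-points pooled fit.
    """
    series, truth = sample_cohort(config)
    exp_results = fit_cohort(series, Family.EXPONENTIAL, starts)
    pow_results = fit_cohort(series, Family.POWER, starts)

    n_runs = len(exp_results)
    wins = sum(
        1 for e, p in zip(exp_results, pow_results) if e.rms < p.rms
    )
    exp_ind = summarize_individuals(exp_results)
    pow_ind = summarize_individuals(pow_results)
    ratios = [
        p.rms / e.rms for e, p in zip(exp_ind, pow_ind) if e.rms > 0
    ]
    mean_ratio = float(np.mean(ratios)) if ratios else float("nan")

    binned = {k: pool_binned(series, k, starts=starts) for k in k_bins_list}
    allp = pool_all_points(series, starts=starts)
    return AggregationReport(
        truth=truth,
        exp_results=exp_results,
        pow_results=pow_results,
        n_runs=n_runs,
        n_exponential_wins=wins,
        win_fraction=wins / n_runs,
        mean_individual_gap_ratio=mean_ratio,
        binned=binned,
        all_points=allp,
    )
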