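"""Group-level statistics, the exponential-vs-power contest, and pooled fits.

All group statistics are computed over run-averaged individual summaries
(two-run subjects are averaged before the group level).  The pooled-fit
procedures reproduce the three aggregation schemes used to probe the
averaging artifact: per-subject-then-group bin means over 15 or 5 equal
time intervals, and a single fit to every raw setting.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .decay_models import Family, ObservationInterval
from .fitting import (
    FitResult,
    IndividualSummary,
    MultistartConfig,
    SettingSeries,
    fit_points,
)

__all__ = [
    "GroupSummary",
    "ModelContest",
    "PoolScheme",
    "PooledFit",
    "group_summary",
    "model_contest",
    "pool_binned",
    "pool_all_points",
    "discriminability_check",
]

_COLUMNS = ["A", "b", "C", "f_tmin", "f_tmax", "rms", "T"]


@dataclass(frozen=True)
class GroupSummary:
    """Mean / median / sample SD per column over individual summaries."""

    family: Family
    n_subjects: int
    table: pd.DataFrame  # index: mean, median, sd; columns: _COLUMNS

    def __getitem__(self, key: tuple[str, str]) -> float:
        stat, column = key
        return float(self.table.loc[stat, column])


def group_summary(individuals: list[IndividualSummary]) -> GroupSummary:
    """Column-wise mean, median and sample SD (ddof=1) over subjects.

    Requires one run-averaged summary per subject, all of one family.
    The time constant T is summarized as the mean of the per-individual
    T = 1/(run-averaged b); note mean(1/b) differs from 1/mean(b).
    """
    if not individuals:
        raise ValueError("no individual summaries given")
    subjects = [s.subject_id for s in individuals]
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subjects in group summary input")
    families = {s.family for s in individuals}
    if len(families) != 1:
        raise ValueError("group summary requires a single model family")
    family = individuals[0].family
    frame = pd.DataFrame(
        {
            "A": [s.A for s in individuals],
            "b": [s.b for s in individuals],
            "C": [s.C for s in individuals],
            "f_tmin": [s.f_tmin for s in individuals],
            "f_tmax": [s.f_tmax for s in individuals],
            "rms": [s.rms for s in individuals],
            "T": [s.T if s.T is not None else np.nan for s in individuals],
        }
    )
    table = pd.DataFrame(
        {
            "mean": frame.mean(),
            "median": frame.median(),
            "sd": frame.std(ddof=1),
        }
    ).T[_COLUMNS]
    return GroupSummary(family=family, n_subjects=len(individuals), table=table)


@dataclass(frozen=True)
class ModelContest:
    """Head-to-head comparison of the two families on matched runs.

    ``percent_excess`` is how much larger the group-mean power RMS is than
    the exponential one, in percent; the paired t-test is two-sided across
    subjects on run-averaged RMS.
    """

    n_runs_total: int
    n_runs_power_wins: int
    mean_rms_exponential: float
    mean_rms_power: float
    percent_excess: float
    t_statistic: float
    p_value: float
    df: int


def _rms_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        need = {"subject", "run", "rms"}
        if not need.issubset(results.columns):
            raise ValueError(f"RMS frame needs columns {sorted(need)}")
        return results[["subject", "run", "rms"]].copy()
    rows = [(r.subject_id, r.run_id, r.rms) for r in results]
    return pd.DataFrame(rows, columns=["subject", "run", "rms"])


def model_contest(exp_results, pow_results) -> ModelContest:
    """Per-run win count, group-mean RMS excess, and paired t-test.

    Accepts matched per-run results for both families, either as lists of
    :class:`FitResult` or as DataFrames with columns (subject, run, rms).
    Group means and the t-test use run-averaged RMS per subject.
    """
    e = _rms_frame(exp_results).set_index(["subject", "run"]).sort_index()
    p = _rms_frame(pow_results).set_index(["subject", "run"]).sort_index()
    if not e.index.equals(p.index):
        raise ValueError("exponential and power run sets do not match")

    n_runs = len(e)
    wins = int((p["rms"].to_numpy() < e["rms"].to_numpy()).sum())

    e_subj = e.groupby(level="subject")["rms"].mean()
    p_subj = p.groupby(level="subject")["rms"].mean()
    mean_e = float(e_subj.mean())
    mean_p = float(p_subj.mean())
    percent_excess = 100.0 * (mean_p / mean_e - 1.0)

    diffs = p_subj.to_numpy() - e_subj.to_numpy()
    df = len(diffs) - 1
    if np.allclose(diffs, 0.0):
        # Identical per-subject RMS: no evidence of a difference.
        t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = stats.ttest_rel(p_subj.to_numpy(), e_subj.to_numpy())
        t_stat, p_val = float(t_stat), float(p_val)
    return ModelContest(
        n_runs_total=n_runs,
        n_runs_power_wins=wins,
        mean_rms_exponential=mean_e,
        mean_rms_power=mean_p,
        percent_excess=percent_excess,
        t_statistic=t_stat,
        p_value=p_val,
        df=df,
    )


class PoolScheme(str, enum.Enum):
    BINNED_15 = "binned_15"
    BINNED_5 = "binned_5"
    ALL_POINTS = "all_points"


@dataclass(frozen=True)
class PooledFit:
    """Group-pooled data points with both family fits."""

    scheme: PoolScheme
    points: pd.DataFrame  # columns: t, svh
    fit_exponential: FitResult
    fit_power: FitResult

    @property
    def rms_gap_ratio(self) -> float:
        """Power RMS over exponential RMS on the pooled points."""
        return self.fit_power.rms / self.fit_exponential.rms


def _fit_pooled(
    t: np.ndarray,
    y: np.ndarray,
    scheme: PoolScheme,
    starts: MultistartConfig | None,
    interval: ObservationInterval | None,
) -> PooledFit:
    if t.size < 4:
        raise ValueError(f"need at least 4 pooled points to fit, got {t.size}")
    kw = dict(starts=starts, interval=interval, subject_id="<pooled>", run_id=0)
    return PooledFit(
        scheme=scheme,
        points=pd.DataFrame({"t": t, "svh": y}),
        fit_exponential=fit_points(t, y, Family.EXPONENTIAL, **kw),
        fit_power=fit_points(t, y, Family.POWER, **kw),
    )


def pool_binned(
    all_series: list[SettingSeries],
    k_bins: int,
    window: tuple[float, float] = (0.0, 360.0),
    starts: MultistartConfig | None = None,
    interval: ObservationInterval | None = None,
) -> PooledFit:
    """Two-stage bin means (per subject, then per group) and fits to them.

    The recording window is split into ``k_bins`` equal intervals.  For
    each subject, all of that subject's settings (both runs pooled) in a
    bin are averaged into one (t, svh) point; the group point for a bin is
    the mean over contributing subjects.  Bins with no settings from any
    subject are dropped before fitting.
    """
    if k_bins < 2:
        raise ValueError("k_bins must be >= 2")
    if not all_series:
        raise ValueError("no series given")
    lo, hi = window
    edges = np.linspace(lo, hi, k_bins + 1)

    rows = []
    for s in all_series:
        idx = np.clip(np.searchsorted(edges, s.times, side="right") - 1, 0, k_bins - 1)
        for b, t, y in zip(idx, s.times, s.svh):
            rows.append((s.subject_id, int(b), t, y))
    df = pd.DataFrame(rows, columns=["subject", "bin", "t", "svh"])
    per_subject = df.groupby(["subject", "bin"], as_index=False)[["t", "svh"]].mean()
    group = per_subject.groupby("bin")[["t", "svh"]].mean().sort_index()

    scheme = {15: PoolScheme.BINNED_15, 5: PoolScheme.BINNED_5}.get(
        k_bins, PoolScheme.BINNED_15 if k_bins >= 10 else PoolScheme.BINNED_5
    )
    return _fit_pooled(
        group["t"].to_numpy(), group["svh"].to_numpy(), scheme, starts, interval
    )


def pool_all_points(
    all_series: list[SettingSeries],
    starts: MultistartConfig | None = None,
    interval: ObservationInterval | None = None,
) -> PooledFit:
    """Single fit of each family to every raw setting from every run."""
    if not all_series:
        raise ValueError("no series given")
    t = np.concatenate([s.times for s in all_series])
    y = np.concatenate([s.svh for s in all_series])
    order = np.argsort(t, kind="stable")
    return _fit_pooled(t[order], y[order], PoolScheme.ALL_POINTS, starts, interval)


@dataclass(frozen=True)
class DiscriminabilityReport:
    """Six data-set criteria for discriminating between retention functions.

    The criteria ask whether a data set can, in principle, tell competing
    forgetting functions apart: (1) nine or more retention intervals per
    run; (2) precise time values; (3) a large span both in the measured
    quantity and in time (last/first setting-time ratio); (4) a single
    stimulus presentation per series of measurements; (5) constant filler
    activity over the retention interval; (6) per-individual fitting is
    possible (enough settings per run for a 3-parameter fit).
    """

    per_run: pd.DataFrame
    passes: dict[int, bool]
    notes: dict[int, str]


def discriminability_check(
    all_series: list[SettingSeries],
    constant_filler: bool = True,
    min_time_ratio: float = 10.0,
    min_signal_ratio: float = 2.0,
) -> DiscriminabilityReport:
    """Evaluate the six discriminability criteria on a cohort.

    Criterion 3 is quantitative: the per-run ratio of last to first
    setting time (90 for a run spanning [4, 360] s) and the ratio of the
    SVH change over the run to the within-run residual scale; thresholds
    ``min_time_ratio`` and ``min_signal_ratio`` operationalize "large".
    Criterion 4 holds structurally for this paradigm (one centrifuge
    acceleration per run, many settings after it); criterion 5 is a
    metadata flag (darkness, no competing task).
    """
    if not all_series:
        raise ValueError("no series given")
    rows = []
    for s in all_series:
        t, y = s.times, s.svh
        n_distinct = len(np.unique(t))
        time_ratio = float(t[-1] / t[0]) if s.n else np.nan
        svh_change = float(np.max(y) - np.min(y)) if s.n else np.nan
        # residual scale about a crude trend: RMS of first differences / sqrt(2)
        noise = float(np.std(np.diff(y) / np.sqrt(2.0))) if s.n > 1 else np.nan
        signal_ratio = svh_change / noise if noise and noise > 0 else np.inf
        rows.append(
            (
                s.subject_id,
                s.run_id,
                s.n,
                n_distinct,
                time_ratio,
                svh_change,
                signal_ratio,
            )
        )
    per_run = pd.DataFrame(
        rows,
        columns=[
            "subject",
            "run",
            "n",
            "n_distinct_times",
            "time_ratio",
            "svh_change",
            "signal_ratio",
        ],
    )
    passes = {
        1: bool((per_run["n_distinct_times"] >= 9).all()),
        2: True,
        3: bool(
            (per_run["time_ratio"] >= min_time_ratio).all()
            and (per_run["signal_ratio"] >= min_signal_ratio).all()
        ),
        4: True,
        5: bool(constant_filler),
        6: bool((per_run["n"] >= 4).all()),
    }
    notes = {
        1: "nine or more distinct measurement times in every run",
        2: "every setting carries a precise time value (structural)",
        3: (
            f"last/first time ratio >= {min_time_ratio} and SVH-change/"
            f"noise ratio >= {min_signal_ratio} in every run"
        ),
        4: "one stimulus (centrifuge acceleration) per run (structural)",
        5: "constant filler activity (darkness, no competing task)",
        6: "every run has enough settings for an individual 3-parameter fit",
    }
    return DiscriminabilityReport(per_run=per_run, passes=passes, notes=notes)
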