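"""Settings-file and table I/O.

Settings files are comma-delimited UTF-8 text with a header row
``subject_id,run_id,t_seconds,svh_degrees``, '#' comment lines, '.'
decimal point.  Times are seconds from the beginning of the G plateau;
SVH is degrees, right tilt positive.  Malformed rows are reported with
their 1-based line numbers.
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decay_models import Family, ObservationInterval
from .fitting import (
    FitResult,
    MultistartConfig,
    SettingSeries,
    summarize_individuals,
)

__all__ = [
    "SettingsFormatError",
    "read_settings",
    "write_settings",
    "write_truth",
    "read_truth",
    "RunConfig",
    "load_config",
    "save_config",
    "render_tables",
    "write_tables",
]

_COLUMNS = ["subject_id", "run_id", "t_seconds", "svh_degrees"]

_HEADER_COMMENT = (
    "# SVH setting series: one row per setting of the luminous line.\n"
    "# t_seconds: time since the beginning of the G plateau.\n"
    "# svh_degrees: deviation from gravitoinertial horizontal; right tilt positive.\n"
)


class SettingsFormatError(ValueError):
    """Malformed settings file; message carries the offending line number."""


def read_settings(path: str | Path) -> list[SettingSeries]:
    """Parse a settings file into validated per-run series.

    Rows are grouped by (subject_id, run_id) in order of first
    appearance; times within each run must be strictly increasing.
    """
    path = Path(path)
    rows: dict[tuple[str, int], list[tuple[float, float, int]]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = None
        for lineno, rec in enumerate(reader, start=1):
            if not rec or rec[0].lstrip().startswith("#"):
                continue
            if header is None:
                header = [c.strip() for c in rec]
                if header != _COLUMNS:
                    raise SettingsFormatError(
                        f"{path}:{lineno}: expected header {','.join(_COLUMNS)}, "
                        f"got {','.join(header)}"
                    )
                continue
            if len(rec) != 4:
                raise SettingsFormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(rec)}"
                )
            subject = rec[0].strip()
            try:
                run = int(rec[1])
                t = float(rec[2])
                y = float(rec[3])
            except ValueError as exc:
                raise SettingsFormatError(f"{path}:{lineno}: {exc}") from exc
            if not (np.isfinite(t) and np.isfinite(y)):
                raise SettingsFormatError(f"{path}:{lineno}: non-finite value")
            rows.setdefault((subject, run), []).append((t, y, lineno))
    if header is None:
        raise SettingsFormatError(f"{path}: empty file (no header)")

    series = []
    for (subject, run), recs in rows.items():
        times = np.array([r[0] for r in recs])
        svh = np.array([r[1] for r in recs])
        bad = np.nonzero(np.diff(times) <= 0)[0]
        if bad.size:
            lineno = recs[int(bad[0]) + 1][2]
            raise SettingsFormatError(
                f"{path}:{lineno}: non-increasing time in series {subject}/{run}"
            )
        try:
            series.append(
                SettingSeries(subject_id=subject, run_id=run, times=times, svh=svh)
            )
        except ValueError as exc:
            lineno = recs[0][2]
            raise SettingsFormatError(f"{path}:{lineno}: {exc}") from exc
    return series


def write_settings(
    path: str | Path, all_series: list[SettingSeries], precision: int = 6
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        fh.write(_HEADER_COMMENT)
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for s in all_series:
            for t, y in zip(s.times, s.svh):
                writer.writerow(
                    [s.subject_id, s.run_id, f"{t:.{precision}f}", f"{y:.{precision}f}"]
                )


def write_truth(path: str | Path, truth: pd.DataFrame) -> None:
    """Sidecar file with the generating parameters of a synthetic cohort."""
    truth.to_csv(path, index=False, float_format="%.10g")


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; round-trips losslessly through YAML."""

    interval: tuple[float, float] = (4.0, 360.0)
    n_starts: int = 64
    b_range_exponential: tuple[float, float] = (1e-4, 2.0)
    b_range_power: tuple[float, float] = (1e-4, 4.0)
    bins: tuple[int, ...] = (15, 5)
    precision_amplitude: int = 1  # decimals for A, C, F columns
    precision_rate: int = 4  # decimals for b
    precision_rms: int = 3
    seed: int = 0
    output_dir: str = "."

    def observation_interval(self) -> ObservationInterval:
        return ObservationInterval(*self.interval)

    def multistart(self) -> MultistartConfig:
        return MultistartConfig(
            n_starts=self.n_starts,
            b_range_exponential=tuple(self.b_range_exponential),
            b_range_power=tuple(self.b_range_power),
        )


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    kwargs = {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return RunConfig(**kwargs)


def save_config(path: str | Path, config: RunConfig) -> None:
    data = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
    }
    Path(path).write_text(
        yaml.safe_dump(data, sort_keys=True), encoding="utf-8"
    )


def _footer(frame: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    stats = pd.DataFrame(
        {
            "Mean": frame[columns].mean(),
            "Median": frame[columns].median(),
            "SD": frame[columns].std(ddof=1),
        }
    ).T
    stats.insert(0, "subject", stats.index)
    return stats


def render_tables(
    exp_results: list[FitResult],
    pow_results: list[FitResult],
    config: RunConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-run parameter tables and the RMS table, with Mean/Median/SD footers.

    Layout mirrors the published tables: one row per subject with run 1
    and run 2 columns for A, b, C, F(t_min), F(t_max); the RMS table
    carries per-run setting counts and both families' RMS.  Footer rows
    are computed on run-averaged values at full precision, then rounded
    (A, C, F to ``precision_amplitude`` decimals, b to ``precision_rate``,
    RMS to ``precision_rms``).
    """
    config = config or RunConfig()
    if not exp_results or not pow_results:
        raise ValueError("no results to render")
    missing = {(r.subject_id, r.run_id) for r in exp_results} ^ {
        (r.subject_id, r.run_id) for r in pow_results
    }
    if missing:
        raise ValueError(f"incomplete results; unmatched runs: {sorted(missing)}")

    out: dict[str, pd.DataFrame] = {}
    for family, results in (
        (Family.EXPONENTIAL, exp_results),
        (Family.POWER, pow_results),
    ):
        wide = _params_table(results, config)
        out[f"params_{family.value}"] = wide
    out["rms"] = _rms_table(exp_results, pow_results, config)
    return out


def _round_cols(frame: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rounded = frame.copy()
    for col in rounded.columns:
        if col.startswith(("A_", "C_", "F")):
            rounded[col] = rounded[col].round(config.precision_amplitude)
        elif col.startswith("b_"):
            rounded[col] = rounded[col].round(config.precision_rate)
        elif col.startswith("rms"):
            rounded[col] = rounded[col].round(config.precision_rms)
    return rounded


def _params_table(results: list[FitResult], config: RunConfig) -> pd.DataFrame:
    lo, hi = config.interval
    rows = {}
    for r in results:
        row = rows.setdefault(r.subject_id, {"subject": r.subject_id})
        row[f"A_run{r.run_id}"] = r.params.A
        row[f"b_run{r.run_id}"] = r.params.b
        row[f"C_run{r.run_id}"] = r.params.C
        row[f"F{lo:g}_run{r.run_id}"] = r.f_tmin
        row[f"F{hi:g}_run{r.run_id}"] = r.f_tmax
    wide = pd.DataFrame(list(rows.values()))
    # run-averaged values feed the footer, mirroring group statistics
    summaries = summarize_individuals(results)
    avg = pd.DataFrame(
        {
            "subject": [s.subject_id for s in summaries],
            "A_avg": [s.A for s in summaries],
            "b_avg": [s.b for s in summaries],
            "C_avg": [s.C for s in summaries],
            f"F{lo:g}_avg": [s.f_tmin for s in summaries],
            f"F{hi:g}_avg": [s.f_tmax for s in summaries],
        }
    )
    footer = _footer(avg, [c for c in avg.columns if c != "subject"])
    footer.columns = ["subject"] + [
        c.replace("_avg", "_run1") for c in avg.columns if c != "subject"
    ]
    table = pd.concat([wide, footer], ignore_index=True)
    return _round_cols(table, config)


def _rms_table(
    exp_results: list[FitResult],
    pow_results: list[FitResult],
    config: RunConfig,
) -> pd.DataFrame:
    pow_by_run = {(r.subject_id, r.run_id): r for r in pow_results}
    rows = {}
    for e in exp_results:
        p = pow_by_run[(e.subject_id, e.run_id)]
        row = rows.setdefault(e.subject_id, {"subject": e.subject_id})
        row[f"n_run{e.run_id}"] = e.n
        row[f"rms_exponential_run{e.run_id}"] = e.rms
        row[f"rms_power_run{e.run_id}"] = p.rms
    wide = pd.DataFrame(list(rows.values()))
    exp_ind = summarize_individuals(exp_results)
    pow_ind = summarize_individuals(pow_results)
    avg = pd.DataFrame(
        {
            "subject": [s.subject_id for s in exp_ind],
            "rms_exponential_run1": [s.rms for s in exp_ind],
            "rms_power_run1": [s.rms for s in pow_ind],
        }
    )
    footer = _footer(avg, ["rms_exponential_run1", "rms_power_run1"])
    table = pd.concat([wide, footer], ignore_index=True)
    return _round_cols(table, config)


def write_tables(
    tables: dict[str, pd.DataFrame], directory: str | Path, prefix: str = ""
) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, frame in tables.items():
        p = directory / f"{prefix}{name}.csv"
        frame.to_csv(p, index=False)
        paths.append(p)
    return paths
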