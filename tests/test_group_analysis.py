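"""Group statistics, the model contest, pooling, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

from svhdecay import (
    CohortConfig,
    Family,
    SettingSeries,
    discriminability_check,
    group_summary,
    model_contest,
    pool_all_points,
    pool_binned,
    sample_cohort,
)
from svhdecay import study


class TestGroupSummaryReproduction:
    """Run-averaging the published per-run values reproduces the published
    group rows."""

    def test_exponential_mean_row(self):
        gs = group_summary(study.individual_summaries("exponential"))
        assert gs.n_subjects == 27
        assert gs["mean", "A"] == pytest.approx(27.76, abs=0.005)
        assert gs["mean", "b"] == pytest.approx(0.01805, abs=5e-5)
        assert gs["mean", "C"] == pytest.approx(0.49, abs=0.01)
        assert gs["mean", "f_tmin"] == pytest.approx(26.49, abs=0.005)
        assert gs["mean", "f_tmax"] == pytest.approx(1.99, abs=0.005)
        assert gs["mean", "T"] == pytest.approx(85.0, abs=1.0)

    def test_exponential_dispersion_row(self):
        gs = group_summary(study.individual_summaries("exponential"))
        assert gs["sd", "A"] == pytest.approx(15.2, abs=0.05)
        assert gs["sd", "C"] == pytest.approx(6.1, abs=0.05)
        assert gs["sd", "b"] == pytest.approx(0.0147, abs=2e-4)
        assert gs["sd", "T"] == pytest.approx(62.0, abs=1.0)

    def test_rms_summary_both_families(self):
        exp_gs = group_summary(study.individual_summaries("exponential"))
        pow_gs = group_summary(study.individual_summaries("power"))
        assert exp_gs["mean", "rms"] == pytest.approx(2.416, abs=5e-4)
        assert exp_gs["median", "rms"] == pytest.approx(2.136, abs=5e-4)
        assert pow_gs["mean", "rms"] == pytest.approx(3.160, abs=5e-4)
        assert pow_gs["median", "rms"] == pytest.approx(3.074, abs=5e-4)

    def test_identical_subjects_degenerate_summary(self):
        one = study.individual_summaries("exponential")[0]
        from dataclasses import replace

        clones = [replace(one, subject_id=f"c{i}") for i in range(5)]
        gs = group_summary(clones)
        assert gs["sd", "A"] == 0.0
        assert gs["mean", "A"] == gs["median", "A"] == one.A

    def test_refuses_duplicate_subjects(self):
        one = study.individual_summaries("exponential")[0]
        with pytest.raises(ValueError, match="duplicate"):
            group_summary([one, one])


class TestModelContest:
    def test_published_rms_values(self):
        contest = model_contest(
            study.run_results("exponential"), study.run_results("power")
        )
        assert contest.n_runs_total == 44
        assert contest.n_runs_power_wins == 4
        assert contest.mean_rms_exponential == pytest.approx(2.416, abs=5e-4)
        assert contest.mean_rms_power == pytest.approx(3.160, abs=5e-4)
        assert contest.percent_excess == pytest.approx(31.0, abs=1.0)
        assert contest.df == 26
        assert contest.p_value < 1e-4
        assert contest.t_statistic > 0

    def test_equal_inputs_yield_null_contest(self):
        runs = study.run_results("exponential")
        contest = model_contest(runs, runs)
        assert contest.n_runs_power_wins == 0
        assert contest.percent_excess == 0.0
        assert contest.p_value == 1.0 and contest.t_statistic == 0.0

    def test_accepts_rms_frames(self):
        frame = study.rms_runs().rename(columns={"rms_exponential": "rms"})
        frame2 = study.rms_runs().rename(columns={"rms_power": "rms"})
        contest = model_contest(frame, frame2)
        assert contest.n_runs_power_wins == 4

    def test_refuses_mismatched_run_sets(self):
        exp_runs = study.run_results("exponential")
        with pytest.raises(ValueError, match="do not match"):
            model_contest(exp_runs, study.run_results("power")[:-1])


def _mini_cohort(n_subjects=6, seed=21, **kw):
    cfg = CohortConfig(n_subjects=n_subjects, n_two_run=n_subjects // 2,
                       seed=seed, **kw)
    return sample_cohort(cfg)[0]


class TestPooling:
    def test_single_subject_pool_equals_own_bin_means(self):
        series = _mini_cohort(n_subjects=1)
        pooled = pool_binned(series, 15)
        s = series[0]
        edges = np.linspace(0, 360, 16)
        idx = np.clip(np.searchsorted(edges, s.times, "right") - 1, 0, 14)
        expected = (
            pd.DataFrame({"bin": idx, "t": s.times, "svh": s.svh})
            .groupby("bin")[["t", "svh"]]
            .mean()
        )
        assert np.allclose(pooled.points["t"], expected["t"])
        assert np.allclose(pooled.points["svh"], expected["svh"])

    @pytest.mark.parametrize("k", [5, 15])
    def test_bin_counts(self, k):
        series = _mini_cohort(n_subjects=8)
        pooled = pool_binned(series, k)
        # default schedule populates every bin of width >= 24 s
        assert len(pooled.points) == k
        assert pooled.fit_exponential.converged
        assert pooled.rms_gap_ratio > 0

    def test_pooling_conserves_settings(self):
        series = _mini_cohort(n_subjects=8)
        total = sum(s.n for s in series)
        pooled = pool_all_points(series)
        assert len(pooled.points) == total

    def test_all_points_handles_tied_times(self):
        t = np.array([4.0, 50.0, 100.0, 200.0, 300.0])
        a = SettingSeries("a", 1, t, 30 * np.exp(-0.01 * t))
        b = SettingSeries("b", 1, t, 20 * np.exp(-0.02 * t))
        pooled = pool_all_points([a, b])
        assert len(pooled.points) == 10

    def test_homogeneous_noiseless_cohort_is_perfectly_exponential(self):
        """Identical noiseless decays: the all-points fit is exact; binned
        fits carry only the Jensen bias of within-bin averaging (mean of a
        convex exponential over a bin of width w exceeds the curve at the
        mean time by at most A b^2 w^2 / 8) and still beat the power fit."""
        A, b = 30.0, 0.015
        t = np.linspace(4, 360, 20)
        series = [
            SettingSeries(f"s{i}", 1, t, A * np.exp(-b * t) + 1.0)
            for i in range(6)
        ]
        allp = pool_all_points(series)
        assert allp.fit_exponential.rms == pytest.approx(0.0, abs=1e-7)
        assert allp.fit_power.rms > allp.fit_exponential.rms
        for k in (15, 5):
            pooled = pool_binned(series, k)
            assert pooled.fit_exponential.rms <= A * b**2 * (360 / k) ** 2 / 8
            assert pooled.fit_power.rms > pooled.fit_exponential.rms

    def test_refuses_empty_and_tiny_inputs(self):
        with pytest.raises(ValueError):
            pool_all_points([])
        t = np.array([4.0, 100.0, 300.0])
        with pytest.raises(ValueError):
            pool_all_points([SettingSeries("a", 1, t, t * 0.0)])


class TestAggregationArtifact:
    def test_heterogeneous_cohort_erodes_exponential_advantage(self, default_cohort):
        """Pooling all points from heterogeneous exponential decays brings
        the power fit nearly level with the exponential fit."""
        series, _ = default_cohort
        from svhdecay import fit_cohort, summarize_individuals

        exp_ind = summarize_individuals(fit_cohort(series, Family.EXPONENTIAL))
        pow_ind = summarize_individuals(fit_cohort(series, Family.POWER))
        mean_ratio = np.mean([p.rms / e.rms for e, p in zip(exp_ind, pow_ind)])
        allp = pool_all_points(series).rms_gap_ratio
        assert allp < mean_ratio
        binned15 = pool_binned(series, 15).rms_gap_ratio
        assert binned15 > 1.0  # grouped bin means still favor the exponential


class TestDiscriminability:
    def test_study_conformant_cohort_passes_all(self):
        series = _mini_cohort(n_subjects=8)
        report = discriminability_check(series)
        assert all(report.passes.values())
        assert (report.per_run["n_distinct_times"] >= 9).all()

    def test_three_point_run_fails_count_criteria(self):
        t = np.array([4.0, 100.0, 300.0])
        report = discriminability_check([SettingSeries("a", 1, t, t * 0.0)])
        assert not report.passes[1]
        assert not report.passes[6]

    def test_time_ratio_for_full_window(self):
        t = np.array([4.0, 100.0, 200.0, 360.0])
        report = discriminability_check([SettingSeries("a", 1, t, t * 0.01)])
        assert report.per_run["time_ratio"].iloc[0] == pytest.approx(90.0)
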