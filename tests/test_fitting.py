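"""Variable-projection fitting: correctness, invariances, run averaging."""

import numpy as np
import pytest

from svhdecay import (
    DecayParams,
    Family,
    MultistartConfig,
    SettingSeries,
    average_runs,
    fit_series,
    sse,
)
from svhdecay.fitting import FitResult

from _oracles import grid_oracle_sse


def make_series(t, y, subject="s", run=1):
    return SettingSeries(subject_id=subject, run_id=run, times=np.asarray(t, float),
                         svh=np.asarray(y, float))


class TestSeriesValidation:
    def test_rejects_nonincreasing_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_series([4.0, 10.0, 10.0], [1, 2, 3])

    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError, match="> 0"):
            make_series([0.0, 5.0], [1, 2])


class TestSse:
    def test_zero_on_generating_curve(self, clean_exponential_series):
        series, (A, b, C) = clean_exponential_series
        p = DecayParams(family="exponential", A=A, b=b, C=C)
        assert sse(p, series) == pytest.approx(0.0, abs=1e-20)

    def test_constant_series_against_matching_asymptote(self):
        series = make_series([4, 50, 100, 200], [7.0] * 4)
        p = DecayParams(family="exponential", A=0.0, b=1.0, C=7.0)
        assert sse(p, series) == 0.0

    def test_hand_computed_five_point_series(self):
        # term-by-term: residuals of y against 10*exp(-0.02 t) + 1
        t = np.array([5.0, 20.0, 60.0, 120.0, 300.0])
        y = np.array([10.0, 8.0, 4.0, 2.0, 1.5])
        p = DecayParams(family="exponential", A=10.0, b=0.02, C=1.0)
        model = 10.0 * np.exp(-0.02 * t) + 1.0
        expected = float(((y - model) ** 2).sum())
        assert sse(p, make_series(t, y)) == pytest.approx(expected, rel=1e-15)

    def test_power_family_rejects_nonpositive_time_in_series(self):
        p = DecayParams(family="power", A=10.0, b=0.5, C=0.0)
        series = make_series([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert np.isfinite(sse(p, series))


class TestFitSeries:
    def test_noiseless_exponential_identifiability(self, clean_exponential_series):
        series, (A, b, C) = clean_exponential_series
        r = fit_series(series, Family.EXPONENTIAL)
        assert r.params.A == pytest.approx(A, rel=1e-6)
        assert r.params.b == pytest.approx(b, rel=1e-6)
        assert r.params.C == pytest.approx(C, rel=1e-6)
        assert r.rms < 1e-8
        assert r.converged
        assert r.n == series.n
        assert r.rms == pytest.approx(np.sqrt(r.sse / r.n))

    def test_noiseless_power_identifiability(self):
        t = np.geomspace(4.0, 360.0, 25)
        y = 40.0 * t ** (-0.6) - 1.5
        r = fit_series(make_series(t, y), Family.POWER)
        assert r.params.A == pytest.approx(40.0, rel=1e-6)
        assert r.params.b == pytest.approx(0.6, rel=1e-6)
        assert r.params.C == pytest.approx(-1.5, rel=1e-6)

    @pytest.mark.parametrize("family", [Family.EXPONENTIAL, Family.POWER])
    def test_matches_grid_oracle_on_noisy_series(self, family):
        rng = np.random.default_rng(77)
        t = np.sort(rng.uniform(4, 360, 22))
        y = 28.0 * np.exp(-0.015 * t) + 1.0 + rng.normal(0, 2.4, t.size)
        r = fit_series(make_series(t, y), family)
        cfg = MultistartConfig()
        oracle = grid_oracle_sse(family.value, t, y, cfg.b_range(family))
        assert r.sse == pytest.approx(oracle, rel=1e-6)

    def test_refuses_short_and_nonfinite_series(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_series(make_series([4, 5, 6], [1, 2, 3]), "exponential")
        with pytest.raises(ValueError, match="non-finite"):
            fit_series(make_series([4, 5, 6, 7], [1, np.nan, 3, 4]), "exponential")

    def test_constant_series_reports_flat_solution(self):
        series = make_series([4, 60, 120, 240, 360], [3.5] * 5)
        r = fit_series(series, Family.EXPONENTIAL)
        assert r.params.A == 0.0
        assert r.params.C == pytest.approx(3.5)
        assert r.sse == pytest.approx(0.0, abs=1e-18)

    def test_scale_equivariance(self):
        """Scaling the data by k scales A, C, rms by k and leaves b fixed."""
        rng = np.random.default_rng(3)
        t = np.sort(rng.uniform(4, 360, 20))
        y = 30 * np.exp(-0.012 * t) + 2 + rng.normal(0, 2, 20)
        k = 3.7
        r1 = fit_series(make_series(t, y), Family.EXPONENTIAL)
        r2 = fit_series(make_series(t, k * y), Family.EXPONENTIAL)
        assert r2.params.b == pytest.approx(r1.params.b, rel=1e-6)
        assert r2.params.A == pytest.approx(k * r1.params.A, rel=1e-6)
        assert r2.params.C == pytest.approx(k * r1.params.C, rel=1e-6)
        assert r2.rms == pytest.approx(k * r1.rms, rel=1e-6)

    def test_time_shift_covariance_exponential(self):
        """Shifting times by d rescales A by exp(b d); b, C, rms unchanged."""
        rng = np.random.default_rng(4)
        t = np.sort(rng.uniform(4, 300, 20))
        y = 25 * np.exp(-0.01 * t) - 1 + rng.normal(0, 1.5, 20)
        d = 30.0
        r1 = fit_series(make_series(t, y), Family.EXPONENTIAL)
        r2 = fit_series(make_series(t + d, y), Family.EXPONENTIAL)
        b = r1.params.b
        assert r2.params.b == pytest.approx(b, rel=1e-5)
        assert r2.params.A == pytest.approx(r1.params.A * np.exp(b * d), rel=1e-4)
        assert r2.params.C == pytest.approx(r1.params.C, abs=1e-4)
        assert r2.rms == pytest.approx(r1.rms, rel=1e-6)

    def test_more_starts_never_increase_final_sse(self):
        rng = np.random.default_rng(9)
        t = np.sort(rng.uniform(4, 360, 18))
        y = 20 * np.exp(-0.03 * t) + rng.normal(0, 2, 18)
        series = make_series(t, y)
        sses = [
            fit_series(series, Family.POWER, MultistartConfig(n_starts=n)).sse
            for n in (8, 16, 64, 128)
        ]
        for a, b in zip(sses, sses[1:]):
            assert b <= a * (1 + 1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(10)
        t = np.sort(rng.uniform(4, 360, 20))
        y = 30 * np.exp(-0.02 * t) + rng.normal(0, 2, 20)
        r1 = fit_series(make_series(t, y), Family.EXPONENTIAL)
        r2 = fit_series(make_series(t, y), Family.EXPONENTIAL)
        assert r1 == r2


class TestAverageRuns:
    def _result(self, subject, run, family, A, b, C, rms, n=20):
        p = DecayParams(family=family, A=A, b=b, C=C)
        from svhdecay import interval_extremes

        lo, hi = interval_extremes(p)
        return FitResult(subject_id=subject, run_id=run, params=p,
                         sse=n * rms**2, rms=rms, n=n, f_tmin=lo, f_tmax=hi,
                         converged=True, n_starts_used=64)

    def test_two_run_arithmetic_means(self):
        # subject 1's published exponential runs: A (45.7, 30.3) -> 38.0,
        # RMS (3.085, 2.304) -> 2.6945
        r1 = self._result("1", 1, "exponential", 45.7, 0.0223, 7.7, 3.085)
        r2 = self._result("1", 2, "exponential", 30.3, 0.0101, 5.6, 2.304)
        s = average_runs([r1, r2])
        assert s.A == pytest.approx(38.0)
        assert s.rms == pytest.approx(2.6945)
        assert s.b == pytest.approx(0.0162)
        assert s.T == pytest.approx(1 / 0.0162)
        assert s.n_runs == 2

    def test_single_run_identity(self):
        r = self._result("18", 1, "exponential", 22.4, 0.0074, -0.5, 2.136)
        s = average_runs([r])
        assert (s.A, s.b, s.C, s.rms) == (22.4, 0.0074, -0.5, 2.136)
        assert s.f_tmin == r.f_tmin and s.f_tmax == r.f_tmax
        assert s.n_runs == 1

    def test_power_family_has_no_time_constant(self):
        r = self._result("5", 1, "power", 51.5, 0.7716, 2.6, 1.593)
        assert average_runs([r]).T is None

    def test_refuses_mixed_subjects_or_families(self):
        a = self._result("1", 1, "exponential", 45.7, 0.0223, 7.7, 3.0)
        b = self._result("2", 1, "exponential", 17.6, 0.0104, 6.6, 3.6)
        with pytest.raises(ValueError, match="mix subjects"):
            average_runs([a, b])
        c = self._result("1", 2, "power", 112.2, 0.2256, -24.7, 4.1)
        with pytest.raises(ValueError, match="mix families"):
            average_runs([a, c])
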