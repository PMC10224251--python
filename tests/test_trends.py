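"""Robust trend estimators against enumeration oracles; selection; projection."""

import numpy as np
import pytest

from isoclim.climate_io import StationSeries
from isoclim.trends import (
    MODEL_ORDER,
    StationMonthSeries,
    build_station_month_series,
    fit_all_models,
    fit_m_estimator,
    fit_mm_estimator,
    fit_ols,
    fit_siegel,
    fit_theil_sen,
    project_station,
    select_best_model,
    selection_frequencies,
)


def theil_sen_oracle(x, y):
    slopes = [
        (y[j] - y[i]) / (x[j] - x[i])
        for i in range(len(x)) for j in range(i + 1, len(x)) if x[j] != x[i]
    ]
    slope = np.median(slopes)
    return slope, np.median(y - slope * x)


def siegel_oracle(x, y):
    n = len(x)
    med = [
        np.median([(y[j] - y[i]) / (x[j] - x[i]) for j in range(n) if j != i])
        for i in range(n)
    ]
    slope = np.median(med)
    return slope, np.median(y - slope * x)


def ols_oracle(x, y):
    A = np.vstack([np.ones_like(x), x]).T
    intercept, slope = np.linalg.solve(A.T @ A, A.T @ y)
    return slope, intercept


class TestExactLines:
    @pytest.mark.parametrize("fitter", [fit_ols, fit_theil_sen, fit_siegel,
                                        fit_m_estimator, fit_mm_estimator])
    def test_exact_line_recovered(self, fitter):
        x = np.arange(1990.0, 2010.0)
        y = 3.0 + 0.25 * x
        f = fitter((x, y))
        assert f.slope == pytest.approx(0.25, abs=1e-8)
        assert f.intercept == pytest.approx(3.0, abs=1e-5)

    def test_theil_sen_small_example(self):
        f = fit_theil_sen((np.array([0.0, 1, 2]), np.array([1.0, 3, 5])))
        assert (f.slope, f.intercept) == (2.0, 1.0)


class TestOracleAgreement:
    def test_theil_sen_outlier_example_matches_enumeration(self):
        x = np.array([0.0, 1, 2, 3])
        y = np.array([0.0, 1, 2, 100])
        slope, intercept = theil_sen_oracle(x, y)
        f = fit_theil_sen((x, y))
        assert f.slope == pytest.approx(slope, abs=1e-12)
        assert f.intercept == pytest.approx(intercept, abs=1e-12)
        # median of {1, 1, 1, 33.33, 49.5, 98}
        assert slope == pytest.approx((1 + 33 + 1 / 3) / 2)

    def test_random_series_match_oracles_exactly(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 31))
            x = np.sort(rng.choice(200, size=n, replace=False)).astype(float)
            y = 0.1 * x + rng.normal(0, 3, n)
            ts, tsi = theil_sen_oracle(x, y)
            f = fit_theil_sen((x, y))
            assert abs(f.slope - ts) < 1e-12 and abs(f.intercept - tsi) < 1e-12
            ss, ssi = siegel_oracle(x, y)
            g = fit_siegel((x, y))
            assert abs(g.slope - ss) < 1e-12 and abs(g.intercept - ssi) < 1e-12
            os, oi = ols_oracle(x, y)
            h = fit_ols((x, y))
            assert abs(h.slope - os) < 1e-9 and abs(h.intercept - oi) < 1e-6

    def test_siegel_breakdown_on_exact_line(self, rng):
        # corrupting floor((n-1)/2) of 21 points leaves the repeated-median fit intact
        x = np.arange(21.0)
        y = 2.0 + 0.5 * x
        bad = rng.choice(21, size=10, replace=False)
        y_bad = y.copy()
        y_bad[bad] += rng.uniform(50, 500, size=10)
        f = fit_siegel((x, y_bad))
        s, i = siegel_oracle(x, y_bad)
        assert f.slope == pytest.approx(s, abs=1e-12)
        assert f.slope == pytest.approx(0.5, abs=1e-9)
        assert f.intercept == pytest.approx(2.0, abs=1e-9)


class TestRobustness:
    def test_m_estimator_closer_to_truth_than_ols_on_outliers(self, rng):
        x = np.arange(20.0)
        y = 1.0 * x
        y[[4, 11, 17]] += [60.0, -80.0, 90.0]
        ols = fit_ols((x, y))
        m = fit_m_estimator((x, y))
        assert abs(m.slope - 1.0) < abs(ols.slope - 1.0)

    def test_mm_estimator_resists_gross_contamination(self, rng):
        x = np.arange(1980.0, 2020.0)
        y = 5.0 + 0.03 * (x - 1980) + rng.normal(0, 0.5, 40)
        bad = rng.choice(40, size=8, replace=False)
        y_bad = y.copy()
        y_bad[bad] += rng.choice([-1, 1], 8) * rng.uniform(5, 10, 8)
        mm = fit_mm_estimator((x, y_bad))
        ols = fit_ols((x, y_bad))
        truth = 0.03
        assert abs(mm.slope - truth) < abs(ols.slope - truth)

    @pytest.mark.parametrize("fitter", [fit_ols, fit_theil_sen, fit_siegel,
                                        fit_m_estimator, fit_mm_estimator])
    def test_equivariance_shift_and_scale(self, fitter, rng):
        x = np.arange(2000.0, 2020.0)
        y = 1.0 + 0.1 * (x - 2000) + rng.normal(0, 0.4, 20)
        f0 = fitter((x, y))
        fc = fitter((x, y + 7.5))
        assert fc.slope == pytest.approx(f0.slope, abs=1e-8)
        assert fc.intercept == pytest.approx(f0.intercept + 7.5, abs=1e-6)
        fk = fitter((x, 3.0 * y))
        assert fk.slope == pytest.approx(3.0 * f0.slope, abs=1e-7)
        assert fk.intercept == pytest.approx(3.0 * f0.intercept, abs=1e-4)

    def test_theil_sen_invariant_under_reordering(self, rng):
        x = np.arange(15.0)
        y = rng.normal(0, 1, 15)
        perm = rng.permutation(15)
        # oracle works on unordered data; the fit API requires sorted years
        s1, i1 = theil_sen_oracle(x, y)
        s2, i2 = theil_sen_oracle(x[perm], y[perm])
        assert s1 == pytest.approx(s2, abs=1e-12) and i1 == pytest.approx(i2, abs=1e-12)


class TestSelection:
    def test_exact_tie_breaks_by_model_order(self):
        # constant series: every model fits exactly (score 0.0) -> first model wins
        x = np.arange(2000.0, 2015.0)
        y = np.full(15, 5.0)
        s = StationMonthSeries("A", "temperature", 1, x, y)
        best = select_best_model(fit_all_models(s), s)
        assert best.model == MODEL_ORDER[0]

    def test_contaminated_series_prefer_robust_models(self, rng):
        wins = []
        for _ in range(50):
            x = np.arange(1980.0, 2020.0)
            y = 5 + 0.03 * (x - 1980) + rng.normal(0, 0.5, 40)
            bad = rng.choice(40, size=8, replace=False)
            y[bad] += rng.choice([-1, 1], 8) * rng.uniform(5, 10, 8)
            s = StationMonthSeries("A", "temperature", 1, x, y)
            wins.append(select_best_model(fit_all_models(s), s).model)
        robust = sum(m not in ("ols",) for m in wins)
        assert robust > len(wins) / 2

    def test_single_fit_returned(self):
        x = np.arange(2000.0, 2012.0)
        y = 0.2 * x
        f = fit_ols((x, y))
        s = StationMonthSeries("A", "temperature", 1, x, y)
        assert select_best_model([f], s) is f

    def test_selection_frequencies_sum_to_100(self, rng):
        fits = [fit_ols((np.arange(10.0), rng.normal(0, 1, 10))) for _ in range(5)]
        fits += [fit_theil_sen((np.arange(10.0), rng.normal(0, 1, 10))) for _ in range(15)]
        freq = selection_frequencies(fits)
        assert freq["percent"].sum() == pytest.approx(100.0)
        assert freq.loc["theil_sen", "percent"] == pytest.approx(75.0)


class TestProjection:
    def _station(self, rng, trend=0.0, noise=0.0):
        years = np.arange(1980, 2020)
        normal = 10 + 8 * -np.cos(2 * np.pi * (np.arange(12) + 0.5) / 12)
        temp = normal[None, :] + trend * (years - 1980)[:, None] \
            + rng.normal(0, noise, (40, 12))
        precip = np.full((40, 12), 60.0)
        return StationSeries("P", -120, 38, 500, years, temp, precip)

    def test_zero_slope_projection_equals_intercept_mean(self, rng):
        s = self._station(rng)
        proj = project_station(s, 2050)
        assert np.allclose(proj.t, s.temp[0], atol=1e-8)
        assert np.allclose(proj.p, 60.0, atol=1e-8)

    def test_linear_trend_extrapolates(self, rng):
        s = self._station(rng, trend=0.03)
        proj = project_station(s, 2050)
        expected = s.temp[0] + 0.03 * (2050 - 1980)
        assert np.allclose(proj.t, expected, atol=1e-6)

    def test_negative_precip_clamped_to_zero(self):
        years = np.arange(2000, 2015)
        precip = np.maximum(10.0 - 1.0 * (years - 2000), 0.0)[:, None] * np.ones(12)
        precip[precip < 0] = 0
        temp = np.full((15, 12), 10.0)
        s = StationSeries("N", -120, 38, 0, years, temp, precip)
        proj = project_station(s, 2050)
        assert np.all(proj.p >= 0.0)

    def test_build_series_counts(self, rng):
        s1 = self._station(rng)
        series = build_station_month_series([s1, s1], "temperature")
        assert len(series) == 24
        assert all(len(x.values) == 40 for x in series)

    def test_short_station_excluded(self, rng):
        years = np.arange(2000, 2005)
        s = StationSeries("S", -120, 38, 0, years,
                          np.full((5, 12), 10.0), np.full((5, 12), 10.0))
        assert build_station_month_series([s], "temperature") == []
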