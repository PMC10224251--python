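"""Robust linear trend fitting and projection of station climate.

For every station, calendar month, and variable (temperature, precipitation)
five linear models are fitted against calendar year: ordinary least squares,
Theil-Sen, Siegel repeated medians, a Huber M-estimator, and an MM-type
high-breakdown estimator. The best model per series is selected by a
residual criterion (default: median absolute residual, which lets the robust
fits win on contaminated series) and evaluated at the target year; projected
indices are then recomputed from the projected monthly climate rather than
trended directly, preserving inter-index identities such as Ic = Tmax - Tmin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .climate_io import MONTHS, StationSeries
from .indices import MonthlyClimatology

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_ORDER",
    "StationMonthSeries",
    "TrendFit",
    "build_station_month_series",
    "fit_ols",
    "fit_theil_sen",
    "fit_siegel",
    "fit_m_estimator",
    "fit_mm_estimator",
    "fit_all_models",
    "select_best_model",
    "selection_frequencies",
    "project_station",
]

#: Declared model order; also the deterministic tie-break order.
MODEL_ORDER = ("ols", "theil_sen", "siegel", "m_estimator", "mm_estimator")

MIN_POINTS = 10


@dataclass
class StationMonthSeries:
    """One station's yearly values for a single calendar month and variable."""

    station_id: str
    variable: str
    month: int
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years/values length mismatch")
        if self.years.size >= 2 and np.any(np.diff(self.years) <= 0):
            raise ValueError("years not strictly increasing")


@dataclass
class TrendFit:
    """A fitted line value = intercept + slope * year."""

    model: str
    slope: float
    intercept: float
    fit_score: float
    n: int
    converged: bool = True

    def predict(self, year: float) -> float:
        return self.intercept + self.slope * year


def build_station_month_series(
    stations: list[StationSeries], variable: str
) -> list[StationMonthSeries]:
    """Decompose complete stations into 12 per-month yearly series each.

    Series shorter than ``MIN_POINTS`` are excluded with a warning.
    """
    if variable not in ("temperature", "precipitation"):
        raise ValueError("variable must be 'temperature' or 'precipitation'")
    out = []
    for s in stations:
        mat = s.temp if variable == "temperature" else s.precip
        if s.years.size < MIN_POINTS:
            logger.warning(
                "station %s: only %d years (<%d); excluded from trend fitting",
                s.station_id, s.years.size, MIN_POINTS,
            )
            continue
        for m in range(MONTHS):
            out.append(
                StationMonthSeries(
                    station_id=s.station_id,
                    variable=variable,
                    month=m + 1,
                    years=s.years,
                    values=mat[:, m],
                )
            )
    return out


def _xy(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, StationMonthSeries):
        return series.years, series.values
    x, y = series
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def fit_ols(series) -> TrendFit:
    """Closed-form least squares line."""
    x, y = _xy(series)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise ValueError("all years equal")
    slope = float(((x - xm) * (y - ym)).sum()) / sxx
    intercept = ym - slope * xm
    return TrendFit("ols", slope, float(intercept), _rmse(x, y, slope, intercept), x.size)


def fit_theil_sen(series) -> TrendFit:
    """Theil-Sen: median pairwise slope; intercept = median(y - slope*x)."""
    x, y = _xy(series)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need >=2 distinct x values")
    slope, intercept, _, _ = stats.theilslopes(y, x, method="joint")
    return TrendFit("theil_sen", float(slope), float(intercept),
                    _rmse(x, y, slope, intercept), x.size)


def fit_siegel(series) -> TrendFit:
    """Siegel repeated medians; intercept = median(y - slope*x)."""
    x, y = _xy(series)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    slope, intercept = stats.siegelslopes(y, x, method="hierarchical")
    return TrendFit("siegel", float(slope), float(intercept),
                    _rmse(x, y, slope, intercept), x.size)


def fit_m_estimator(series, t: float = 1.345, max_iter: int = 50) -> TrendFit:
    """Huber M-estimator via iteratively reweighted least squares (MAD scale)."""
    x, y = _xy(series)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    X = sm.add_constant(x)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=t)).fit(maxiter=max_iter)
        intercept, slope = float(res.params[0]), float(res.params[1])
        converged = np.all(np.isfinite(res.params))
    except Exception:  # pragma: no cover - singular designs
        converged = False
    if not converged:
        logger.warning("m_estimator did not converge; falling back to OLS")
        f = fit_ols((x, y))
        return TrendFit("m_estimator", f.slope, f.intercept, f.fit_score, x.size, False)
    return TrendFit("m_estimator", slope, intercept, _rmse(x, y, slope, intercept), x.size)


def fit_mm_estimator(series, c: float = 4.685, max_iter: int = 100, tol: float = 1e-10) -> TrendFit:
    """MM-type estimator: Theil-Sen initial fit, frozen MAD scale, bisquare IRLS.

    The high-breakdown initial estimate makes the subsequent redescending
    M-step resistant to gross outliers; the procedure is fully deterministic
    (no subsampling).
    """
    x, y = _xy(series)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    init = fit_theil_sen((x, y))
    resid0 = y - init.predict(x)
    scale = 1.4826 * float(np.median(np.abs(resid0 - np.median(resid0))))
    if scale <= 1e-12:
        # initial fit is (near) exact for a majority of points
        return TrendFit("mm_estimator", init.slope, init.intercept,
                        _rmse(x, y, init.slope, init.intercept), x.size)
    slope, intercept = init.slope, init.intercept
    converged = False
    for _ in range(max_iter):
        u = (y - (intercept + slope * x)) / (c * scale)
        w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
        if w.sum() <= 0 or np.unique(x[w > 0]).size < 2:
            break
        sw = w.sum()
        xm = (w * x).sum() / sw
        ym = (w * y).sum() / sw
        sxx = (w * (x - xm) ** 2).sum()
        new_slope = float((w * (x - xm) * (y - ym)).sum() / sxx)
        new_intercept = float(ym - new_slope * xm)
        if abs(new_slope - slope) < tol and abs(new_intercept - intercept) < tol:
            slope, intercept = new_slope, new_intercept
            converged = True
            break
        slope, intercept = new_slope, new_intercept
    else:
        converged = True  # iteration cap reached with finite estimates
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        logger.warning("mm_estimator diverged; falling back to OLS")
        f = fit_ols((x, y))
        return TrendFit("mm_estimator", f.slope, f.intercept, f.fit_score, x.size, False)
    return TrendFit("mm_estimator", slope, intercept,
                    _rmse(x, y, slope, intercept), x.size, converged)


_FITTERS = {
    "ols": fit_ols,
    "theil_sen": fit_theil_sen,
    "siegel": fit_siegel,
    "m_estimator": fit_m_estimator,
    "mm_estimator": fit_mm_estimator,
}


def _rmse(x, y, slope, intercept) -> float:
    r = y - (intercept + slope * x)
    return float(np.sqrt(np.mean(r**2)))


def _median_abs_residual(x, y, fit: TrendFit) -> float:
    return float(np.median(np.abs(y - fit.predict(x))))


def fit_all_models(series) -> list[TrendFit]:
    """Fit the five models to one series, in declared order."""
    fits = []
    for name in MODEL_ORDER:
        try:
            fits.append(_FITTERS[name](series))
        except ValueError:
            logger.warning("%s failed on series; skipped", name)
    if not fits:
        raise ValueError("no model could be fitted")
    return fits


def select_best_model(
    fits: list[TrendFit], series, criterion: str = "median_abs_residual"
) -> TrendFit:
    """Pick the fit minimising the residual criterion on the observed years.

    ``median_abs_residual`` (default) or ``rmse``. Ties break by declared
    model order. The chosen fit's ``fit_score`` is set to its criterion value.
    """
    if not fits:
        raise ValueError("no fits to select from")
    x, y = _xy(series)
    if criterion == "median_abs_residual":
        score = lambda f: _median_abs_residual(x, y, f)
    elif criterion == "rmse":
        score = lambda f: _rmse(x, y, f.slope, f.intercept)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    order = {m: i for i, m in enumerate(MODEL_ORDER)}
    best = min(fits, key=lambda f: (score(f), order.get(f.model, 99)))
    best.fit_score = score(best)
    return best


def selection_frequencies(chosen: list[TrendFit]) -> pd.DataFrame:
    """Percentage of series won by each model (cf. the best-model tally)."""
    counts = pd.Series([f.model for f in chosen]).value_counts()
    pct = 100.0 * counts / counts.sum()
    return pd.DataFrame({"count": counts, "percent": pct.round(1)}).reindex(
        [m for m in MODEL_ORDER if m in counts.index]
    )


def fit_station(
    station: StationSeries, criterion: str = "median_abs_residual"
) -> dict[tuple[str, int], TrendFit]:
    """Selected best fit per (variable, month) for one complete station."""
    fits: dict[tuple[str, int], TrendFit] = {}
    for variable in ("temperature", "precipitation"):
        for s in build_station_month_series([station], variable):
            fits[(variable, s.month)] = select_best_model(
                fit_all_models(s), s, criterion=criterion
            )
    return fits


def project_station(
    station: StationSeries,
    target_year: int = 2050,
    criterion: str = "median_abs_residual",
    fits: dict[tuple[str, int], TrendFit] | None = None,
    zero_slopes: bool = False,
) -> MonthlyClimatology:
    """Projected monthly climatology at ``target_year`` from the selected fits.

    Precipitation is floored at 0 mm. ``zero_slopes`` evaluates the fits with
    their slopes forced to zero (no-trend control pathway).
    """
    fits = fits if fits is not None else fit_station(station, criterion=criterion)
    t = np.empty(MONTHS)
    p = np.empty(MONTHS)
    for m in range(1, MONTHS + 1):
        ft = fits[("temperature", m)]
        fp = fits[("precipitation", m)]
        if zero_slopes:
            t[m - 1] = ft.intercept + ft.slope * np.mean(station.years)
            p[m - 1] = fp.intercept + fp.slope * np.mean(station.years)
        else:
            t[m - 1] = ft.predict(target_year)
            p[m - 1] = fp.predict(target_year)
    p = np.maximum(p, 0.0)
    hemisphere = "north" if station.latitude >= 0 else "south"
    return MonthlyClimatology(t=t, p=p, hemisphere=hemisphere)
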