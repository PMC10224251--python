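"""Bioclimatic parameters and indices of the Rivas-Martinez worldwide system.

All quantities are computed from a 12-month climatology of mean temperature
``Ti`` (degC) and precipitation ``Pi`` (mm):

* ``Tp = 10 * sum(Ti for Ti > 0)`` — positive annual temperature, tenths of degC;
* ``Pp = sum(Pi for months with Ti > 0)`` — positive annual precipitation, mm;
* ``Ic = Tmax - Tmin`` — simple continentality index (annual thermal range);
* ``It = 10 * (Tavg + 2 * Tmin)`` — thermicity index;
* ``Itc`` — It compensated for extreme oceanicity/continentality via a
  piecewise function of Ic;
* ``Io = 10 * Pp / Tp`` — annual ombrothermic index;
* ``Ios1..Ios4`` — summer ombrothermic indices over nested summer windows
  (warmest summer month; two hottest summer months; summer quarter; summer
  quarter plus the preceding month), each ``sum(P) / sum(T)`` over the window.

Index values that are undefined (positive temperature sum <= 0 over the
relevant window) are reported as NaN, never silently as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .climate_io import StationSeries

__all__ = [
    "MonthlyClimatology",
    "BioclimVector",
    "CompensationTable",
    "DEFAULT_COMPENSATION",
    "INDEX_ORDER",
    "climatology_of",
    "positive_sums",
    "thermal_extremes",
    "thermicity",
    "ombrothermic",
    "summer_quarter",
    "summer_ombrothermic",
    "compute_indices",
]

#: Characterisation-table variable order.
INDEX_ORDER = [
    "tavg", "tmin", "tmax", "pavg", "pp", "it", "itc",
    "tp", "ic", "io", "ios2", "ios3", "ios4",
]


@dataclass
class MonthlyClimatology:
    """Twelve monthly normals of mean temperature (degC) and precipitation (mm)."""

    t: np.ndarray
    p: np.ndarray
    hemisphere: str = "north"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != (12,) or self.p.shape != (12,):
            raise ValueError("climatology requires exactly 12 monthly values")
        if np.any(self.p < 0):
            raise ValueError("negative monthly precipitation")
        if self.hemisphere not in ("north", "south"):
            raise ValueError("hemisphere must be 'north' or 'south'")


@dataclass
class BioclimVector:
    """The 13 bioclimatic parameters/indices plus elevation and soil order."""

    tavg: float
    pavg: float
    tp: float
    pp: float
    tmax: float
    tmin: float
    ic: float
    it: float
    itc: float
    io: float
    ios1: float
    ios2: float
    ios3: float
    ios4: float
    elevation: float | None = None
    soil_order: int | None = None

    def as_dict(self, include_ios1: bool = True) -> dict[str, float]:
        d = {k: getattr(self, k) for k in INDEX_ORDER}
        if include_ios1:
            d["ios1"] = self.ios1
        if self.elevation is not None:
            d["elevation"] = self.elevation
        if self.soil_order is not None:
            d["soil_order"] = self.soil_order
        return d


@dataclass
class CompensationTable:
    """Piecewise compensation C(Ic) added to It to obtain Itc.

    Segments are ``(ic_lo, ic_hi, base, slope)``: for Ic in (ic_lo, ic_hi],
    ``C = base + slope * (Ic - ic_lo)``. Ic values inside ``neutral`` get C=0.
    Defaults follow the Rivas-Martinez 2011 system: no compensation for
    Ic in [9, 18]; oceanic territories (Ic < 9) are penalised; continental
    territories (Ic > 18) are compensated with increasingly steep slopes.
    """

    neutral: tuple[float, float] = (9.0, 18.0)
    below_slope: float = 10.0
    above_segments: tuple[tuple[float, float, float, float], ...] = (
        (18.0, 21.0, 0.0, 5.0),
        (21.0, 28.0, 15.0, 10.0),
        (28.0, 46.0, 85.0, 30.0),
        (46.0, 66.0, 625.0, 60.0),
    )

    def compensation(self, ic: float) -> float:
        lo, hi = self.neutral
        if lo <= ic <= hi:
            return 0.0
        if ic < lo:
            return -self.below_slope * (lo - ic)
        for seg_lo, seg_hi, base, slope in self.above_segments:
            if seg_lo < ic <= seg_hi:
                return base + slope * (ic - seg_lo)
        seg_lo, seg_hi, base, slope = self.above_segments[-1]
        return base + slope * (seg_hi - seg_lo)


DEFAULT_COMPENSATION = CompensationTable()


def climatology_of(station: StationSeries, year_range=None) -> MonthlyClimatology:
    """Period normals: per-month mean over the selected years.

    ``year_range`` is an inclusive ``(first, last)`` pair or an iterable of
    years; ``None`` uses every year on record. The station must be complete
    (post-imputation).
    """
    if not station.is_complete():
        raise ValueError(f"station {station.station_id}: series incomplete; impute first")
    if year_range is None:
        mask = np.ones(station.years.size, dtype=bool)
    else:
        yr = tuple(year_range)
        if len(yr) == 2 and np.isscalar(yr[0]):
            mask = (station.years >= yr[0]) & (station.years <= yr[1])
        else:
            mask = np.isin(station.years, np.asarray(yr))
    if not mask.any():
        raise ValueError(
            f"station {station.station_id}: year range disjoint from record "
            f"{station.years.min()}-{station.years.max()}"
        )
    hemisphere = "north" if station.latitude >= 0 else "south"
    return MonthlyClimatology(
        t=station.temp[mask].mean(axis=0),
        p=station.precip[mask].mean(axis=0),
        hemisphere=hemisphere,
    )


def positive_sums(c: MonthlyClimatology) -> tuple[float, float]:
    """(Tp, Pp): sums restricted to months with mean temperature above 0 degC."""
    pos = c.t > 0.0
    tp = 10.0 * float(c.t[pos].sum())
    pp = float(c.p[pos].sum())
    return tp, pp


def thermal_extremes(c: MonthlyClimatology) -> tuple[float, float, float]:
    """(Tmax, Tmin, Ic): warmest/coldest monthly means and their difference."""
    tmax = float(c.t.max())
    tmin = float(c.t.min())
    return tmax, tmin, tmax - tmin


def thermicity(
    c: MonthlyClimatology, compensation: CompensationTable = DEFAULT_COMPENSATION
) -> tuple[float, float]:
    """(It, Itc): thermicity index and its continentality-compensated form."""
    tavg = float(c.t.mean())
    tmax, tmin, ic = thermal_extremes(c)
    it = 10.0 * (tavg + 2.0 * tmin)
    itc = it + compensation.compensation(ic)
    return it, itc


def ombrothermic(c: MonthlyClimatology) -> float:
    """Annual ombrothermic index Io = 10 * Pp / Tp (NaN when Tp <= 0)."""
    tp, pp = positive_sums(c)
    if tp <= 0.0:
        return float("nan")
    return 10.0 * pp / tp


def summer_quarter(c: MonthlyClimatology, mode: str = "warmest") -> tuple[int, int, int]:
    """0-based month indices of the summer quarter.

    ``warmest`` (default): the warmest three consecutive calendar months of
    the climatology (circular; ties broken by earliest start). ``fixed``:
    Jun-Aug in the northern hemisphere, Dec-Feb in the southern.
    """
    if mode == "fixed":
        return (5, 6, 7) if c.hemisphere == "north" else (11, 0, 1)
    if mode != "warmest":
        raise ValueError(f"unknown summer-quarter mode {mode!r}")
    best_start, best_sum = 0, -np.inf
    for start in range(12):
        idx = [(start + k) % 12 for k in range(3)]
        s = float(c.t[idx].sum())
        if s > best_sum + 1e-12:
            best_start, best_sum = start, s
    return tuple((best_start + k) % 12 for k in range(3))


def _window_ratio(c: MonthlyClimatology, months) -> float:
    months = list(months)
    t_sum = float(c.t[months].sum())
    if t_sum <= 0.0:
        return float("nan")
    return float(c.p[months].sum()) / t_sum


def summer_ombrothermic(
    c: MonthlyClimatology, quarter_mode: str = "warmest"
) -> tuple[float, float, float, float]:
    """(Ios1, Ios2, Ios3, Ios4) over nested summer windows.

    Ios1: warmest summer-quarter month; Ios2: the two hottest summer-quarter
    months (ties broken by calendar order); Ios3: the summer quarter; Ios4:
    the summer quarter plus the preceding calendar month. Each equals
    ``sum(P) / sum(T)`` over its window (the factors of ten cancel).
    """
    q = summer_quarter(c, mode=quarter_mode)
    order = sorted(q, key=lambda m: (-c.t[m], m))
    ios1 = _window_ratio(c, order[:1])
    ios2 = _window_ratio(c, order[:2])
    ios3 = _window_ratio(c, q)
    ios4 = _window_ratio(c, [(q[0] - 1) % 12, *q])
    return ios1, ios2, ios3, ios4


def compute_indices(
    c: MonthlyClimatology,
    elevation: float | None = None,
    soil_order: int | None = None,
    compensation: CompensationTable = DEFAULT_COMPENSATION,
    quarter_mode: str = "warmest",
) -> BioclimVector:
    """Assemble the full bioclimatic vector for one location/period."""
    tp, pp = positive_sums(c)
    tmax, tmin, ic = thermal_extremes(c)
    it, itc = thermicity(c, compensation)
    io = ombrothermic(c)
    if tp > 0.0 and pp == 0.0:
        io = 0.0
    ios1, ios2, ios3, ios4 = summer_ombrothermic(c, quarter_mode=quarter_mode)
    return BioclimVector(
        tavg=float(c.t.mean()),
        pavg=float(c.p.sum()),
        tp=tp,
        pp=pp,
        tmax=tmax,
        tmin=tmin,
        ic=ic,
        it=it,
        itc=itc,
        io=io,
        ios1=ios1,
        ios2=ios2,
        ios3=ios3,
        ios4=ios4,
        elevation=elevation,
        soil_order=soil_order,
    )
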