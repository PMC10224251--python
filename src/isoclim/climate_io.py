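"""Station climate and occurrence-record ingestion, quality control and cleaning.

Station tables are long-format CSV (one row per station/year/month) and are
assembled into :class:`StationSeries` objects holding ``year x 12`` matrices of
monthly mean temperature (degC) and monthly precipitation totals (mm).
Occurrence tables follow the GBIF simple-export convention and are carried as
pandas DataFrames with columns ``species, longitude, latitude, elevation``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

MONTHS = 12

#: Default column mapping for station CSVs.
STATION_DIALECT = {
    "station_id": "station_id",
    "lon": "lon",
    "lat": "lat",
    "elev": "elev",
    "year": "year",
    "month": "month",
    "tmean": "tmean",
    "prcp": "prcp",
}

#: Default column mapping for occurrence CSVs (GBIF simple export).
OCCURRENCE_DIALECT = {
    "species": "species",
    "longitude": "decimalLongitude",
    "latitude": "decimalLatitude",
    "elevation": "elevation",
}


@dataclass
class StationSeries:
    """Monthly temperature/precipitation series for one weather station.

    ``temp`` and ``precip`` are ``(n_years, 12)`` float arrays with NaN for
    missing cells. ``years`` is strictly increasing.
    """

    station_id: str
    longitude: float
    latitude: float
    elevation: float
    years: np.ndarray
    temp: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.temp = np.asarray(self.temp, dtype=float)
        self.precip = np.asarray(self.precip, dtype=float)
        if self.temp.shape != (self.years.size, MONTHS):
            raise ValueError(
                f"station {self.station_id}: temp shape {self.temp.shape} "
                f"!= ({self.years.size}, {MONTHS})"
            )
        if self.precip.shape != self.temp.shape:
            raise ValueError(f"station {self.station_id}: temp/precip shape mismatch")
        if self.years.size and np.any(np.diff(self.years) <= 0):
            raise ValueError(f"station {self.station_id}: years not strictly increasing")
        with np.errstate(invalid="ignore"):
            if np.any(self.precip < 0):
                raise ValueError(f"station {self.station_id}: negative precipitation")

    @property
    def missing_fraction(self) -> float:
        """Missing-cell fraction pooled over temperature and precipitation."""
        total = self.temp.size + self.precip.size
        missing = int(np.isnan(self.temp).sum() + np.isnan(self.precip).sum())
        return missing / total if total else 0.0

    def is_complete(self) -> bool:
        return not (np.isnan(self.temp).any() or np.isnan(self.precip).any())


def read_station_records(path, dialect: dict | None = None) -> list[StationSeries]:
    """Read a long-format station CSV into a list of :class:`StationSeries`.

    Unparseable numeric entries become missing values (NaN), never zero.
    Duplicate (station, year, month) rows raise ``ValueError`` naming the key.
    """
    cols = dict(STATION_DIALECT, **(dialect or {}))
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no station rows")
    missing_cols = [c for c in cols.values() if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")

    key = [cols["station_id"], cols["year"], cols["month"]]
    dup = df.duplicated(subset=key, keep=False)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise ValueError(f"duplicate station record for key {tuple(first)}")

    for c in (cols["tmean"], cols["prcp"], cols["lon"], cols["lat"], cols["elev"]):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    stations: list[StationSeries] = []
    for sid, grp in df.groupby(cols["station_id"], sort=True):
        years = np.sort(grp[cols["year"]].unique())
        year_index = {y: i for i, y in enumerate(years)}
        temp = np.full((years.size, MONTHS), np.nan)
        precip = np.full((years.size, MONTHS), np.nan)
        rows = grp[cols["year"]].map(year_index).to_numpy()
        mcol = grp[cols["month"]].to_numpy(dtype=int)
        if np.any((mcol < 1) | (mcol > 12)):
            raise ValueError(f"station {sid}: month outside 1..12")
        temp[rows, mcol - 1] = grp[cols["tmean"]].to_numpy()
        precip[rows, mcol - 1] = grp[cols["prcp"]].to_numpy()
        meta = grp.iloc[0]
        stations.append(
            StationSeries(
                station_id=str(sid),
                longitude=float(meta[cols["lon"]]),
                latitude=float(meta[cols["lat"]]),
                elevation=float(meta[cols["elev"]]),
                years=years,
                temp=temp,
                precip=precip,
            )
        )
    return stations


def write_station_records(stations: list[StationSeries], path) -> None:
    """Write stations back to the long CSV dialect read by ``read_station_records``."""
    rows = []
    for s in stations:
        for i, y in enumerate(s.years):
            for m in range(MONTHS):
                rows.append(
                    (s.station_id, s.longitude, s.latitude, s.elevation, int(y), m + 1,
                     s.temp[i, m], s.precip[i, m])
                )
    pd.DataFrame(
        rows, columns=["station_id", "lon", "lat", "elev", "year", "month", "tmean", "prcp"]
    ).to_csv(path, index=False)


def qc_filter_stations(
    stations: list[StationSeries], max_missing_fraction: float = 0.10
) -> tuple[list[StationSeries], pd.DataFrame]:
    """Keep stations whose pooled missing fraction is strictly below the gate.

    Returns (retained stations, rejection report). The report has one row per
    rejected station with its missing fraction.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must lie in [0, 1]")
    kept, rejected = [], []
    for s in stations:
        frac = s.missing_fraction
        if frac < max_missing_fraction:
            kept.append(s)
        else:
            rejected.append((s.station_id, frac))
    report = pd.DataFrame(rejected, columns=["station_id", "missing_fraction"])
    logger.info("qc_filter_stations: kept %d of %d stations", len(kept), len(stations))
    return kept, report


def impute_monthly_means(station: StationSeries) -> StationSeries:
    """Fill missing cells with the station's long-term mean for that calendar month.

    Observed cells are returned bit-identical. A calendar month with no
    observation at all (per variable) raises ``ValueError``.
    """
    out = {}
    for name, mat in (("temperature", station.temp), ("precipitation", station.precip)):
        filled = mat.copy()
        for m in range(MONTHS):
            col = mat[:, m]
            obs = ~np.isnan(col)
            if not obs.any():
                raise ValueError(
                    f"station {station.station_id}: {name} month {m + 1} entirely missing"
                )
            if (~obs).any():
                filled[~obs, m] = col[obs].mean()
        out[name] = filled
    return replace(station, temp=out["temperature"], precip=out["precipitation"])


def read_occurrences(path, dialect: dict | None = None) -> pd.DataFrame:
    """Read occurrence records; returns columns species/longitude/latitude/elevation.

    Rows with an unparseable or out-of-range coordinate, or an empty species
    name, are dropped (count logged). Elevation is optional (NaN when absent).
    """
    cols = dict(OCCURRENCE_DIALECT, **(dialect or {}))
    df = pd.read_csv(path)
    n_in = len(df)
    out = pd.DataFrame(
        {
            "species": df.get(cols["species"], pd.Series(dtype=str)).astype(str),
            "longitude": pd.to_numeric(df.get(cols["longitude"]), errors="coerce"),
            "latitude": pd.to_numeric(df.get(cols["latitude"]), errors="coerce"),
        }
    )
    if cols["elevation"] in df.columns:
        out["elevation"] = pd.to_numeric(df[cols["elevation"]], errors="coerce")
    else:
        out["elevation"] = np.nan
    ok = (
        out["species"].str.strip().ne("")
        & out["longitude"].between(-180, 180)
        & out["latitude"].between(-90, 90)
        & np.isfinite(out["longitude"])
        & np.isfinite(out["latitude"])
    )
    out = out[ok].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"{path}: no parseable occurrence rows")
    logger.info("read_occurrences: %d of %d rows parseable", len(out), n_in)
    return out


def clean_occurrences(
    records: pd.DataFrame,
    region: BaseGeometry,
    dedup_precision: int = 3,
) -> tuple[pd.DataFrame, dict]:
    """Drop duplicate, imprecise, and out-of-region occurrence records.

    Reasons, applied in order per record:

    * ``no_precise_locality`` — absent or (0, 0) coordinates;
    * ``outside_region`` — point not covered by the region polygon;
    * ``duplicate`` — same (species, rounded lon, rounded lat) as a kept record,
      with coordinates rounded to ``dedup_precision`` decimals (3 ~ 110 m).

    Returns (cleaned records, report dict with per-reason counts).
    """
    df = records.reset_index(drop=True)
    report = {"in": len(df), "no_precise_locality": 0, "outside_region": 0, "duplicate": 0}

    imprecise = (
        ~np.isfinite(df["longitude"])
        | ~np.isfinite(df["latitude"])
        | ((df["longitude"] == 0.0) & (df["latitude"] == 0.0))
    )
    report["no_precise_locality"] = int(imprecise.sum())
    df = df[~imprecise]

    inside = df.apply(
        lambda r: region.covers(Point(r["longitude"], r["latitude"])), axis=1
    ) if len(df) else pd.Series(dtype=bool)
    report["outside_region"] = int((~inside).sum()) if len(df) else 0
    df = df[inside] if len(df) else df

    key = pd.DataFrame(
        {
            "species": df["species"],
            "lon": df["longitude"].round(dedup_precision),
            "lat": df["latitude"].round(dedup_precision),
        }
    )
    dup = key.duplicated(keep="first")
    report["duplicate"] = int(dup.sum())
    df = df[~dup.to_numpy()] if len(df) else df

    out = df.reset_index(drop=True)
    report["out"] = len(out)
    logger.info("clean_occurrences: %s", report)
    return out, report
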