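"""Synthetic landscapes, station networks, climate series, and occurrences.

Every pipeline stage gets a known ground truth: a smooth DEM with a soil-order
raster banded by elevation; stations placed on distinct cells; monthly series
built as latitude/elevation-dependent normals + Mediterranean (winter-wet)
seasonality + linear interannual trend + independent Gaussian noise, with
optional gross-outlier contamination and missingness; and occurrence points
sampled from cells whose true bioclimatic vector lies inside a prescribed
envelope box.

All draws are keyed on ``(seed, stage tag)`` so each artifact is reproducible
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .climate_io import MONTHS, StationSeries
from .indices import MonthlyClimatology, compute_indices
from .isobioclimate import macrobioclimate_test
from .surfaces import GridSpec, RasterLayer

__all__ = [
    "ScenarioConfig",
    "full_scale_config",
    "gen_landscape",
    "gen_stations",
    "gen_climate",
    "gen_occurrences",
    "true_climatology",
    "true_variable_layers",
]

_TAG_LANDSCAPE, _TAG_STATIONS, _TAG_CLIMATE, _TAG_OCCURRENCES = 11, 13, 17, 19


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic study scenario.

    Defaults describe a Mediterranean mountain landscape observed 1980-2019:
    a -6.5 degC/km lapse rate, a winter-wet annual precipitation cycle whose
    summer months stay dry enough to satisfy the two-consecutive-month
    ``P < 2T`` criterion at low elevations, a +0.03 degC/yr warming trend,
    and 0.5 degC monthly temperature noise.
    """

    seed: int = 0
    grid: GridSpec = field(
        default_factory=lambda: GridSpec(west=-124.0, north=42.0, cell=0.1,
                                         n_cols=60, n_rows=60)
    )
    n_stations: int = 100
    year_start: int = 1980
    year_end: int = 2019
    # landscape
    max_elev: float = 3000.0
    n_soil_orders: int = 5
    # climate normals
    t_sea_level: float = 17.0        # degC at sea level on the southern edge
    t_lat_gradient: float = -0.8     # degC per degree latitude northward
    lapse_rate: float = -6.5         # degC per km of elevation
    t_seasonal_amp: float = 8.0      # degC, annual sinusoid semi-amplitude at the coast
    t_amp_east_gain: float = 0.06    # relative amplitude growth per degree inland
    p_annual_base: float = 700.0     # mm at the coast at sea level
    p_elev_gain: float = 0.3         # relative orographic gain per km
    coast_gradient: float = -0.10    # relative drying per degree east of coast
    winter_amp: float = 0.95         # winter-wet weighting of the annual cycle
    # trends and noise
    trend_t: float = 0.03            # degC per year, every month
    trend_p: float = -0.002          # relative precipitation change per year
    noise_t: float = 0.5             # degC sd per monthly value
    noise_p: float = 0.25            # precipitation sd as a fraction of the monthly normal
    missing_fraction: float = 0.02
    contamination_fraction: float = 0.0  # fraction of outlier years per series
    check_mediterranean: bool = True

    def __post_init__(self) -> None:
        for frac in (self.missing_fraction, self.contamination_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_stations < 3:
            raise ValueError("need at least 3 stations")
        if self.year_end - self.year_start + 1 < 10:
            raise ValueError("span must cover at least 10 years")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)


def full_scale_config(seed: int = 0) -> ScenarioConfig:
    """Preset mirroring the study design's scale: 177 stations over 40 years."""
    return ScenarioConfig(seed=seed, n_stations=177)


def _rng(cfg: ScenarioConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def gen_landscape(cfg: ScenarioConfig) -> tuple[RasterLayer, RasterLayer]:
    """(DEM, soil-order) rasters: a north-south ridge plus seeded smooth noise.

    Soil codes 1..k are elevation bands perturbed by noise, so soils correlate
    with (but are not determined by) elevation.
    """
    rng = _rng(cfg, _TAG_LANDSCAPE)
    g = cfg.grid
    lon, lat = g.cell_centers()
    # ridge along a meridian two-thirds of the way east, rising northward
    ridge_lon = g.west + 0.66 * (g.east - g.west)
    ridge = np.exp(-((lon - ridge_lon) ** 2) / (2 * (0.2 * (g.east - g.west)) ** 2))
    northness = (lat - g.south) / (g.north - g.south)
    rough = rng.normal(0.0, 1.0, size=(g.n_rows + 8, g.n_cols + 8))
    kernel = np.outer(np.hanning(9), np.hanning(9))
    kernel /= kernel.sum()
    from scipy.signal import convolve2d

    smooth = convolve2d(rough, kernel, mode="valid")
    smooth = (smooth - smooth.min()) / (smooth.max() - smooth.min() + 1e-12)
    dem_vals = cfg.max_elev * np.clip(0.75 * ridge + 0.15 * northness + 0.25 * smooth, 0, 1)
    dem = RasterLayer(grid=g, values=dem_vals)

    k = cfg.n_soil_orders
    jitter = rng.normal(0.0, 0.05 * cfg.max_elev, size=dem_vals.shape)
    edges = np.quantile(dem_vals, np.linspace(0, 1, k + 1)[1:-1])
    soil_vals = 1.0 + np.digitize(dem_vals + jitter, edges)
    soil = RasterLayer(grid=g, values=soil_vals, semantics="categorical")
    return dem, soil


def gen_stations(cfg: ScenarioConfig, dem: RasterLayer) -> pd.DataFrame:
    """Seeded uniform station placement on distinct grid cells."""
    g = cfg.grid
    n_cells = g.n_rows * g.n_cols
    if cfg.n_stations > n_cells:
        raise ValueError("more stations than grid cells")
    rng = _rng(cfg, _TAG_STATIONS)
    flat = rng.choice(n_cells, size=cfg.n_stations, replace=False)
    rows, cols = np.unravel_index(flat, (g.n_rows, g.n_cols))
    lon = g.west + (cols + 0.5) * g.cell
    lat = g.north - (rows + 0.5) * g.cell
    return pd.DataFrame(
        {
            "station_id": [f"S{i:04d}" for i in range(cfg.n_stations)],
            "lon": lon,
            "lat": lat,
            "elevation": dem.values[rows, cols],
            "row": rows,
            "col": cols,
        }
    )


def _monthly_normals(cfg: ScenarioConfig, lon, lat, elev):
    """Noise-free monthly (t, p) normals at the trend anchor year."""
    m = np.arange(1, MONTHS + 1)
    seasonal = -np.cos(2 * np.pi * (m - 0.5) / 12.0)  # -1 in January, +1 in July
    # annual thermal range grows inland (continentality gradient)
    amp = cfg.t_seasonal_amp * (1.0 + cfg.t_amp_east_gain * (np.asarray(lon) - cfg.grid.west))
    t = (
        cfg.t_sea_level
        + cfg.t_lat_gradient * (np.asarray(lat) - cfg.grid.south)
        + cfg.lapse_rate * np.asarray(elev) / 1000.0
        + amp * seasonal
    )
    p_annual = (
        cfg.p_annual_base
        * (1.0 + cfg.p_elev_gain * np.asarray(elev) / 1000.0)
        * np.clip(1.0 + cfg.coast_gradient * (np.asarray(lon) - cfg.grid.west), 0.05, None)
    )
    weights = (1.0 + cfg.winter_amp * np.cos(2 * np.pi * (m - 0.5) / 12.0)) / 12.0
    p = p_annual * weights
    return t, p


def true_climatology(
    cfg: ScenarioConfig, lon: float, lat: float, elev: float, at_year: float | None = None
) -> MonthlyClimatology:
    """Ground-truth climatology at a location.

    ``at_year=None`` evaluates the trend at the mid-point of the observation
    span (what a period mean over the full record recovers); otherwise at the
    given calendar year.
    """
    t, p = _monthly_normals(cfg, lon, lat, elev)
    year = np.mean(cfg.years) if at_year is None else float(at_year)
    dt = year - cfg.year_start
    t = t + cfg.trend_t * dt
    p = np.maximum(p * (1.0 + cfg.trend_p * dt), 0.0)
    return MonthlyClimatology(t=t, p=p)


def true_variable_layers(
    cfg: ScenarioConfig, dem: RasterLayer, at_year: float | None = None
) -> dict[str, RasterLayer]:
    """Noise-free rasters of the 13 indices plus elevation on the scenario grid."""
    g = cfg.grid
    lon, lat = g.cell_centers()
    fields: dict[str, np.ndarray] = {}
    for r in range(g.n_rows):
        for c in range(g.n_cols):
            clim = true_climatology(cfg, lon[r, c], lat[r, c], dem.values[r, c], at_year)
            v = compute_indices(clim, elevation=dem.values[r, c])
            for name, val in v.as_dict(include_ios1=False).items():
                fields.setdefault(name, np.empty((g.n_rows, g.n_cols)))[r, c] = val
    return {name: RasterLayer(grid=g, values=vals) for name, vals in fields.items()}


def gen_climate(cfg: ScenarioConfig, stations: pd.DataFrame) -> list[StationSeries]:
    """Monthly series per station: normals + trend + noise (+ outliers, gaps)."""
    rng = _rng(cfg, _TAG_CLIMATE)
    years = cfg.years
    dt = (years - cfg.year_start)[:, None]
    out: list[StationSeries] = []
    for rec in stations.itertuples(index=False):
        t0, p0 = _monthly_normals(cfg, rec.lon, rec.lat, rec.elevation)
        temp = t0[None, :] + cfg.trend_t * dt + rng.normal(0.0, cfg.noise_t, (years.size, MONTHS))
        p_sd = cfg.noise_p * p0  # noise scales with the monthly normal
        precip = np.maximum(
            p0[None, :] * (1.0 + cfg.trend_p * dt)
            + rng.normal(0.0, 1.0, (years.size, MONTHS)) * p_sd[None, :],
            0.0,
        )
        if cfg.contamination_fraction > 0:
            n_bad = int(round(cfg.contamination_fraction * years.size))
            for m in range(MONTHS):
                bad = rng.choice(years.size, size=n_bad, replace=False)
                sign = rng.choice([-1.0, 1.0], size=n_bad)
                temp[bad, m] += sign * rng.uniform(10, 20, n_bad) * cfg.noise_t
                precip[bad, m] = precip[bad, m] * rng.uniform(4, 8, n_bad) + 50.0
        if cfg.missing_fraction > 0:
            for mat in (temp, precip):
                mask = rng.random(mat.shape) < cfg.missing_fraction
                mat[mask] = np.nan
        out.append(
            StationSeries(
                station_id=rec.station_id,
                longitude=rec.lon,
                latitude=rec.lat,
                elevation=rec.elevation,
                years=years,
                temp=temp,
                precip=precip,
            )
        )
    if cfg.check_mediterranean:
        low = stations.loc[stations["elevation"].idxmin()]
        clim = true_climatology(cfg, low["lon"], low["lat"], low["elevation"])
        assert macrobioclimate_test(clim) == "Mediterranean", (
            "scenario self-check failed: lowest station is not Mediterranean"
        )
    return out


def gen_occurrences(
    cfg: ScenarioConfig,
    layers: dict[str, RasterLayer],
    species: str,
    box: dict[str, tuple[float, float]],
    soil_layer: RasterLayer | None = None,
    soil_orders: frozenset | None = None,
    n: int = 200,
    junk_fraction: float = 0.0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Occurrences sampled from cells whose true vector lies inside ``box``.

    ``exhaustive=True`` returns one record per admissible cell (ignoring
    ``n``). ``junk_fraction`` appends that fraction of junk records (exact
    duplicates, (0,0)-coordinate points, and out-of-region points in equal
    measure) to exercise occurrence cleaning.
    """
    rng = _rng(cfg, _TAG_OCCURRENCES)
    g = cfg.grid
    admissible = np.ones((g.n_rows, g.n_cols), dtype=bool)
    for var, (lo, hi) in box.items():
        admissible &= (layers[var].values >= lo) & (layers[var].values <= hi)
    if soil_layer is not None and soil_orders:
        admissible &= np.isin(soil_layer.values, list(soil_orders))
    rows, cols = np.nonzero(admissible)
    if rows.size == 0:
        raise ValueError(f"{species}: envelope box admits no grid cell")
    if exhaustive:
        idx = np.arange(rows.size)
    else:
        idx = rng.choice(rows.size, size=n, replace=rows.size < n)
    lon = g.west + (cols[idx] + 0.5) * g.cell
    lat = g.north - (rows[idx] + 0.5) * g.cell
    elev = (
        layers["elevation"].values[rows[idx], cols[idx]]
        if "elevation" in layers
        else np.full(idx.size, np.nan)
    )
    df = pd.DataFrame(
        {"species": species, "longitude": lon, "latitude": lat, "elevation": elev}
    )
    if junk_fraction > 0:
        n_junk = int(round(junk_fraction * len(df)))
        kinds = rng.integers(0, 3, size=n_junk)
        junk_rows = []
        for kind in kinds:
            if kind == 0 and len(df):  # exact duplicate of a kept record
                junk_rows.append(df.iloc[int(rng.integers(len(df)))].to_dict())
            elif kind == 1:  # no precise locality
                junk_rows.append(
                    {"species": species, "longitude": 0.0, "latitude": 0.0,
                     "elevation": np.nan}
                )
            else:  # far outside the study region
                junk_rows.append(
                    {"species": species,
                     "longitude": g.east + 5.0 + float(rng.random()),
                     "latitude": g.south - 5.0 - float(rng.random()),
                     "elevation": np.nan}
                )
        df = pd.concat([df, pd.DataFrame(junk_rows)], ignore_index=True)
    return df
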