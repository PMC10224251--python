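"""End-to-end orchestration of the bioclimatic suitability analysis.

Stages (each also callable on its own):

1. characterise — QC + gap-fill stations, compute period climatologies and
   bioclimatic vectors, interpolate index surfaces, sample them at occurrence
   points, and build per-species envelopes and isobioclimate summaries.
2. project — fit the five trend models per station/month/variable, select the
   best by the configured criterion, and project monthly climate to the
   target year; indices are recomputed from the projected climate.
3. suitability — build current and future index surfaces, apply the envelope
   CON logic at both periods, and derive gain/unstable/stable change maps and
   percentages.

A run manifest (config hash, seed, stage timings, versions, model-selection
summary) is written alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box as shapely_box

from . import __version__
from .climate_io import (
    StationSeries,
    clean_occurrences,
    impute_monthly_means,
    qc_filter_stations,
)
from .indices import INDEX_ORDER, climatology_of, compute_indices
from .isobioclimate import default_tables, diagnose, species_isobioclimate_summary
from .suitability import (
    build_envelope,
    change_map,
    suitability_map,
    summarize_change,
    summarize_envelope,
)
from .surfaces import GridSpec, RasterLayer, interpolate, sample_at_points
from .synthetic import ScenarioConfig, gen_climate, gen_landscape, gen_occurrences, gen_stations, true_variable_layers
from .trends import fit_station, project_station, selection_frequencies

logger = logging.getLogger(__name__)

__all__ = [
    "characterise_stations",
    "build_index_surfaces",
    "run_characterise",
    "run_project",
    "run_suitability",
    "run_all",
]

#: Continuous variables entering envelopes (13 indices + elevation).
ENVELOPE_VARIABLES = INDEX_ORDER + ["elevation"]


def characterise_stations(
    stations: list[StationSeries],
    year_range=None,
    max_missing_fraction: float = 0.10,
) -> tuple[pd.DataFrame, list[StationSeries], pd.DataFrame]:
    """QC, impute, and compute the bioclimatic vector per retained station.

    Returns (station index table, imputed stations, QC rejection report).
    """
    kept, qc_report = qc_filter_stations(stations, max_missing_fraction)
    if not kept:
        raise ValueError("no station passed quality control")
    imputed = [impute_monthly_means(s) for s in kept]
    rows = []
    for s in imputed:
        clim = climatology_of(s, year_range)
        v = compute_indices(clim, elevation=s.elevation)
        rows.append(
            {"station_id": s.station_id, "lon": s.longitude, "lat": s.latitude,
             **v.as_dict()}
        )
    return pd.DataFrame(rows), imputed, qc_report


def build_index_surfaces(
    station_table: pd.DataFrame,
    grid: GridSpec,
    method: str = "ordinary_kriging",
    params: dict | None = None,
    variables: list[str] | None = None,
) -> dict[str, RasterLayer]:
    """Interpolate one raster per bioclimatic variable from station values."""
    variables = variables or INDEX_ORDER
    lon = station_table["lon"].to_numpy()
    lat = station_table["lat"].to_numpy()
    layers = {}
    for var in variables:
        vals = station_table[var].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        layers[var] = interpolate((lon[ok], lat[ok], vals[ok]), grid, method, params)
    return layers


def run_characterise(
    stations: list[StationSeries],
    occurrences: pd.DataFrame,
    grid: GridSpec,
    dem: RasterLayer,
    soil: RasterLayer | None = None,
    year_range=None,
    method: str = "ordinary_kriging",
    rarity_fraction: float = 0.05,
) -> dict:
    """Characterisation stage: station vectors, surfaces, envelopes, diagnoses.

    Occurrences are cleaned against the grid's bounding box, attributed with
    the interpolated index surfaces (elevation from the DEM, soil order from
    the soil raster), and summarised per species. Qualitative isobioclimate
    summaries use the diagnosis of each occurrence's nearest retained station,
    since the monthly structure needed for the macrobioclimate test exists
    only at stations.
    """
    station_table, imputed, qc_report = characterise_stations(stations, year_range)
    region = shapely_box(grid.west, grid.south, grid.east, grid.north)
    occ, occ_report = clean_occurrences(occurrences, region)

    layers = build_index_surfaces(station_table, grid, method=method)
    layers["elevation"] = dem

    values = {
        var: sample_at_points(layers[var], occ["longitude"], occ["latitude"])
        for var in ENVELOPE_VARIABLES
    }
    frame = pd.DataFrame(values)
    if soil is not None:
        frame["soil_order"] = sample_at_points(soil, occ["longitude"], occ["latitude"])
    frame["species"] = occ["species"].to_numpy()

    # nearest retained station per occurrence, for qualitative diagnosis
    st_lon = station_table["lon"].to_numpy()
    st_lat = station_table["lat"].to_numpy()
    d2 = (
        (occ["longitude"].to_numpy()[:, None] - st_lon[None, :]) ** 2
        + (occ["latitude"].to_numpy()[:, None] - st_lat[None, :]) ** 2
    )
    nearest = d2.argmin(axis=1)
    tables = default_tables()
    station_diag = {}
    for i, s in enumerate(imputed):
        clim = climatology_of(s, year_range)
        v = compute_indices(clim, elevation=s.elevation)
        station_diag[i] = diagnose(v, clim, tables)

    envelopes, summaries, isobioclimates = {}, {}, {}
    for species, grp in frame.groupby("species", sort=True):
        env = build_envelope(grp.drop(columns=["species"]), str(species))
        envelopes[str(species)] = env
        summaries[str(species)] = summarize_envelope(env)
        diags = [station_diag[nearest[i]] for i in grp.index]
        isobioclimates[str(species)] = species_isobioclimate_summary(
            diags, rarity_fraction
        )
    return {
        "station_table": station_table,
        "stations": imputed,
        "qc_report": qc_report,
        "occurrences": occ,
        "occurrence_report": occ_report,
        "occurrence_values": frame,
        "layers": layers,
        "envelopes": envelopes,
        "envelope_tables": summaries,
        "isobioclimates": isobioclimates,
    }


def run_project(
    stations: list[StationSeries],
    target_year: int = 2050,
    criterion: str = "median_abs_residual",
    zero_slopes: bool = False,
) -> dict:
    """Projection stage: per-station best fits and projected climatologies."""
    projections, fit_rows, chosen = {}, [], []
    for s in stations:
        fits = fit_station(s, criterion=criterion)
        projections[s.station_id] = project_station(
            s, target_year, fits=fits, zero_slopes=zero_slopes
        )
        for (variable, month), f in fits.items():
            chosen.append(f)
            fit_rows.append(
                {"station_id": s.station_id, "variable": variable, "month": month,
                 "model": f.model, "slope": f.slope, "intercept": f.intercept,
                 "fit_score": f.fit_score}
            )
    fit_report = pd.DataFrame(fit_rows)
    freq = {
        variable: selection_frequencies(
            [c for c, r in zip(chosen, fit_rows) if r["variable"] == variable]
        )
        for variable in ("temperature", "precipitation")
    }
    return {
        "projections": projections,
        "fit_report": fit_report,
        "selection_frequencies": freq,
        "target_year": target_year,
        "criterion": criterion,
    }


def run_suitability(
    characterisation: dict,
    projection: dict,
    grid: GridSpec,
    dem: RasterLayer,
    soil: RasterLayer | None = None,
    method: str = "ordinary_kriging",
    use_soil: bool = True,
) -> dict:
    """Suitability stage: current/future masks, change maps, percentages."""
    current_layers = dict(characterisation["layers"])
    station_table = characterisation["station_table"]

    future_rows = []
    for s in characterisation["stations"]:
        clim = projection["projections"][s.station_id]
        v = compute_indices(clim, elevation=s.elevation)
        future_rows.append(
            {"station_id": s.station_id, "lon": s.longitude, "lat": s.latitude,
             **v.as_dict()}
        )
    future_table = pd.DataFrame(future_rows)
    future_layers = build_index_surfaces(future_table, grid, method=method)
    future_layers["elevation"] = dem

    results = {}
    for species, env in characterisation["envelopes"].items():
        per_level = {}
        for level in ("suitable", "optimal"):
            cur = suitability_map(env, current_layers, level, soil, use_soil)
            fut = suitability_map(env, future_layers, level, soil, use_soil)
            ch = change_map(cur, fut, level)
            per_level[level] = {
                "current": cur,
                "future": fut,
                "change": ch,
                "percentages": summarize_change(ch),
            }
        results[species] = per_level
    percent_table = pd.DataFrame(
        [
            {"species": sp, "level": lv, **res[lv]["percentages"]}
            for sp, res in results.items()
            for lv in ("suitable", "optimal")
        ]
    )
    return {
        "future_table": future_table,
        "future_layers": future_layers,
        "species": results,
        "percentages": percent_table,
    }


def _config_hash(cfg: ScenarioConfig) -> str:
    payload = json.dumps(
        {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
         for k, v in asdict(cfg).items()},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_all(
    cfg: ScenarioConfig,
    species_boxes: dict[str, dict] | None = None,
    n_occurrences: int = 200,
    target_year: int = 2050,
    method: str = "ordinary_kriging",
    criterion: str = "median_abs_residual",
    use_soil: bool = False,
    outdir=None,
) -> dict:
    """Full synthetic study: simulate, characterise, project, map change.

    ``species_boxes`` maps species name -> ground-truth envelope box
    (variable -> (lo, hi) on the true noise-free layers); when omitted, one
    cool-climate species occupying the coldest quarter of the landscape is
    used. Outputs (tables as CSV, manifest as JSON) land under ``outdir``
    when given.
    """
    t0 = time.perf_counter()
    timings = {}

    dem, soil = gen_landscape(cfg)
    station_locs = gen_stations(cfg, dem)
    stations = gen_climate(cfg, station_locs)
    truth = true_variable_layers(cfg, dem)
    truth_with_elev = dict(truth)
    if species_boxes is None:
        tavg = truth["tavg"].values
        species_boxes = {
            "synthetic_cold_conifer": {
                "tavg": (float(tavg.min()), float(np.quantile(tavg, 0.25)))
            }
        }
    occs = [
        gen_occurrences(cfg, truth_with_elev, name, box, soil_layer=soil,
                        n=n_occurrences)
        for name, box in species_boxes.items()
    ]
    occurrences = pd.concat(occs, ignore_index=True)
    timings["simulate"] = time.perf_counter() - t0

    t1 = time.perf_counter()
    char = run_characterise(stations, occurrences, cfg.grid, dem, soil, method=method)
    timings["characterise"] = time.perf_counter() - t1

    t2 = time.perf_counter()
    proj = run_project(char["stations"], target_year=target_year, criterion=criterion)
    timings["project"] = time.perf_counter() - t2

    t3 = time.perf_counter()
    suit = run_suitability(char, proj, cfg.grid, dem, soil, method=method,
                           use_soil=use_soil)
    timings["suitability"] = time.perf_counter() - t3

    manifest = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "version": __version__,
        "criterion": criterion,
        "target_year": target_year,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
        "stations_in": len(stations),
        "stations_kept": len(char["stations"]),
        "selection_frequencies": {
            var: df["percent"].to_dict()
            for var, df in proj["selection_frequencies"].items()
        },
    }
    result = {"characterise": char, "project": proj, "suitability": suit,
              "manifest": manifest, "dem": dem, "soil": soil,
              "truth_layers": truth}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        char["station_table"].to_csv(outdir / "station_indices.csv", index=False)
        char["qc_report"].to_csv(outdir / "qc_rejections.csv", index=False)
        proj["fit_report"].to_csv(outdir / "trend_fits.csv", index=False)
        suit["percentages"].to_csv(outdir / "change_percentages.csv", index=False)
        for sp, table in char["envelope_tables"].items():
            table.to_csv(outdir / f"envelope_{sp}.csv", index=False)
        tmp = outdir / "manifest.json.tmp"
        tmp.write_text(json.dumps(manifest, indent=2))
        tmp.rename(outdir / "manifest.json")
    return result
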