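"""Rectilinear climate envelopes, Boolean suitability rasters, and change maps.

A species envelope stores, per bioclimatic variable, the min/Q1/Q3/max of the
values sampled at its occurrence points, plus the set of soil orders it was
observed on. A cell is *suitable* when every continuous variable lies inside
[min, max] (inclusive) and its soil order is admissible; *optimal* uses
[Q1, Q3]. Change between a reference-period map and a future map is coded per
cell as never / gain / unstable / stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import INDEX_ORDER
from .surfaces import GridSpec, RasterLayer

logger = logging.getLogger(__name__)

__all__ = [
    "CHANGE_CODES",
    "SpeciesEnvelope",
    "ChangeRaster",
    "build_envelope",
    "con_mask",
    "suitability_map",
    "change_map",
    "summarize_change",
    "summarize_envelope",
    "render_characterisation",
]

#: Cell codes of a change raster.
CHANGE_CODES = {"never": 0, "gain": 1, "unstable": 2, "stable": 3}

#: Pretty names used in characterisation tables, in report order.
DISPLAY_NAMES = {
    "tavg": "Tavg", "tmin": "Tmin", "tmax": "Tmax", "pavg": "Pavg", "pp": "Pp",
    "it": "It", "itc": "Itc", "tp": "Tp", "ic": "Ic", "io": "Io",
    "ios2": "Ios2", "ios3": "Ios3", "ios4": "Ios4", "elevation": "Elevation",
}


@dataclass
class SpeciesEnvelope:
    """Per-variable (min, Q1, Q3, max) intervals plus admissible soil orders."""

    species: str
    variables: dict[str, tuple[float, float, float, float]]
    soil_orders: frozenset
    n_occurrences: int

    def __post_init__(self) -> None:
        for v, (mn, q1, q3, mx) in self.variables.items():
            if not (mn <= q1 <= q3 <= mx):
                raise ValueError(f"{self.species}/{v}: min<=Q1<=Q3<=max violated")

    def interval(self, variable: str, level: str) -> tuple[float, float]:
        mn, q1, q3, mx = self.variables[variable]
        return (mn, mx) if level == "suitable" else (q1, q3)


@dataclass
class ChangeRaster:
    """Per-cell change category between a reference and a future binary map."""

    grid: GridSpec
    codes: np.ndarray
    level: str

    def count(self, category: str) -> int:
        return int((self.codes == CHANGE_CODES[category]).sum())


def build_envelope(
    values: pd.DataFrame,
    species: str,
    soil_column: str = "soil_order",
    quantile_method: str = "linear",
) -> SpeciesEnvelope:
    """Envelope from per-occurrence variable vectors.

    ``values`` has one row per occurrence and one column per continuous
    variable (plus an optional soil-order column). Rows with any missing
    value are dropped with a warning; fewer than 4 complete rows is an error.
    Quartiles use the configured estimator (default: linear interpolation of
    order statistics).
    """
    df = values.copy()
    soil: frozenset = frozenset()
    if soil_column in df.columns:
        soil_vals = df[soil_column]
        df = df.drop(columns=[soil_column])
    else:
        soil_vals = None
    complete = df.notna().all(axis=1)
    if (~complete).any():
        logger.warning(
            "build_envelope(%s): dropping %d occurrence(s) with missing values",
            species, int((~complete).sum()),
        )
    df = df[complete]
    if len(df) < 4:
        raise ValueError(f"{species}: need >=4 complete occurrence vectors, got {len(df)}")
    if soil_vals is not None:
        soil = frozenset(int(s) for s in soil_vals[complete].dropna().unique())
    variables = {}
    for col in df.columns:
        arr = df[col].to_numpy(dtype=float)
        q1, q3 = np.quantile(arr, [0.25, 0.75], method=quantile_method)
        variables[col] = (float(arr.min()), float(q1), float(q3), float(arr.max()))
    return SpeciesEnvelope(
        species=species,
        variables=variables,
        soil_orders=soil,
        n_occurrences=len(df),
    )


def con_mask(layer: RasterLayer, lo: float, hi: float, atol: float = 1e-6) -> RasterLayer:
    """Conditional (CON) raster: 1 where lo <= value <= hi, else 0.

    Bounds are inclusive; missing cells map to 0 (absence). ``atol`` absorbs
    floating-point noise at the interval boundaries: envelope bounds are
    themselves sampled surface values, so exact-boundary cells are the rule,
    not the exception, and ratio indices (Ios over a near-zero temperature
    sum) can amplify last-bit differences by several orders of magnitude.
    The default is still far below any physical variation between cells.
    """
    if lo > hi:
        raise ValueError("lo must not exceed hi")
    with np.errstate(invalid="ignore"):
        mask = (layer.values >= lo - atol) & (layer.values <= hi + atol)
    return RasterLayer(grid=layer.grid, values=mask.astype(float), semantics="categorical")


def suitability_map(
    envelope: SpeciesEnvelope,
    layers: dict[str, RasterLayer],
    level: str = "suitable",
    soil_layer: RasterLayer | None = None,
    use_soil: bool = True,
) -> RasterLayer:
    """Binary presence raster: conjunction of per-variable CON masks.

    ``layers`` maps variable name -> raster (elevation included as an
    ordinary continuous variable when present in the envelope). The soil
    criterion is a hard set-membership AND, toggleable via ``use_soil``.
    """
    if level not in ("suitable", "optimal"):
        raise ValueError("level must be 'suitable' or 'optimal'")
    grids = {id(l.grid): l.grid for l in layers.values()}
    ref = next(iter(layers.values())).grid
    for l in layers.values():
        if l.grid != ref:
            raise ValueError("all variable layers must share one grid")
    out = np.ones((ref.n_rows, ref.n_cols), dtype=bool)
    for var in envelope.variables:
        if var not in layers:
            raise ValueError(f"missing raster layer for envelope variable {var!r}")
        lo, hi = envelope.interval(var, level)
        out &= con_mask(layers[var], lo, hi).values.astype(bool)
    if use_soil and soil_layer is not None and envelope.soil_orders:
        if soil_layer.grid != ref:
            raise ValueError("soil layer grid mismatch")
        out &= np.isin(soil_layer.values, list(envelope.soil_orders))
    return RasterLayer(grid=ref, values=out.astype(float), semantics="categorical")


def change_map(current: RasterLayer, future: RasterLayer, level: str = "suitable") -> ChangeRaster:
    """Per-cell change category from two binary presence maps.

    (0,0) -> never; (0,1) -> gain; (1,0) -> unstable; (1,1) -> stable.
    """
    if current.grid != future.grid:
        raise ValueError("current/future grids differ")
    cur = current.values.astype(bool)
    fut = future.values.astype(bool)
    codes = np.full(cur.shape, CHANGE_CODES["never"], dtype=np.uint8)
    codes[~cur & fut] = CHANGE_CODES["gain"]
    codes[cur & ~fut] = CHANGE_CODES["unstable"]
    codes[cur & fut] = CHANGE_CODES["stable"]
    return ChangeRaster(grid=current.grid, codes=codes, level=level)


def summarize_change(change: ChangeRaster) -> dict[str, float]:
    """Gain/unstable/stable percentages relative to the current (reference) area.

    Current area = unstable + stable cells; gain is also expressed against it
    (so gain may exceed 100 in principle). Zero current area yields NaNs.
    """
    gain = change.count("gain")
    unstable = change.count("unstable")
    stable = change.count("stable")
    current = unstable + stable
    if current == 0:
        return {"gain": float("nan"), "unstable": float("nan"), "stable": float("nan")}
    return {
        "gain": 100.0 * gain / current,
        "unstable": 100.0 * unstable / current,
        "stable": 100.0 * stable / current,
    }


def summarize_envelope(envelope: SpeciesEnvelope, decimals: int = 1) -> pd.DataFrame:
    """Characterisation table: one row per variable with min/Q1/Q3/max.

    Rows follow the standard report order (Tavg, Tmin, Tmax, Pavg, Pp, It,
    Itc, Tp, Ic, Io, Ios2, Ios3, Ios4, then any extras), rounded to one
    decimal by default.
    """
    order = [v for v in INDEX_ORDER if v in envelope.variables]
    order += [v for v in envelope.variables if v not in order]
    rows = []
    for v in order:
        mn, q1, q3, mx = envelope.variables[v]
        rows.append(
            {
                "variable": DISPLAY_NAMES.get(v, v),
                "min": round(mn, decimals),
                "q1": round(q1, decimals),
                "q3": round(q3, decimals),
                "max": round(mx, decimals),
            }
        )
    return pd.DataFrame(rows)


def render_characterisation(envelope: SpeciesEnvelope, decimals: int = 1) -> str:
    """Monospace one-line-per-variable rendering: ``min (Q1-Q3) max``.

    A quartile interval that collapses after rounding is rendered as a single
    bracketed value.
    """
    table = summarize_envelope(envelope, decimals=decimals)
    lines = [f"{envelope.species} (n={envelope.n_occurrences})"]
    for _, r in table.iterrows():
        iqr = f"({r.q1})" if r.q1 == r.q3 else f"({r.q1}-{r.q3})"
        lines.append(f"  {r.variable}: {r['min']} {iqr} {r['max']}")
    return "\n".join(lines)
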