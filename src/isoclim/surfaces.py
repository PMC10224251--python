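"""Gridded surfaces: interpolation of station values and point sampling.

Rasters are cell-centre registered, addressed by (row, col) with row 0 the
northernmost row, on a lon/lat WGS84 grid. Continuous surfaces are built from
station points by ordinary kriging (spherical or linear variogram fitted to
the empirical semivariogram) with an inverse-distance-weighting fallback.
Rasters persist as plain-text ESRI ASCII grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GridSpec",
    "RasterLayer",
    "interpolate",
    "sample_at_points",
    "write_ascii_grid",
    "read_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: west/north edges, cell size, and shape."""

    west: float
    north: float
    cell: float
    n_cols: int
    n_rows: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) 2-D arrays of cell-centre coordinates."""
        lon = self.west + (np.arange(self.n_cols) + 0.5) * self.cell
        lat = self.north - (np.arange(self.n_rows) + 0.5) * self.cell
        return np.meshgrid(lon, lat)

    def rowcol(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Containing (row, col) for points; half-open cell intervals."""
        col = np.floor((np.asarray(lon) - self.west) / self.cell).astype(int)
        row = np.floor((self.north - np.asarray(lat)) / self.cell).astype(int)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.rowcol(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


@dataclass
class RasterLayer:
    """A gridded field; NaN marks missing cells."""

    grid: GridSpec
    values: np.ndarray
    semantics: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError(
                f"raster shape {self.values.shape} != grid "
                f"({self.grid.n_rows}, {self.grid.n_cols})"
            )
        if self.semantics not in ("continuous", "categorical"):
            raise ValueError("semantics must be 'continuous' or 'categorical'")


def _idw(px, py, pv, qx, qy, power: float = 2.0, eps: float = 1e-9) -> np.ndarray:
    d = np.hypot(qx[:, None] - px[None, :], qy[:, None] - py[None, :])
    out = np.empty(qx.size)
    exact = d < eps
    has_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[exact] = 0.0
    out = (w * pv[None, :]).sum(axis=1) / w.sum(axis=1)
    if has_exact.any():
        idx = exact[has_exact].argmax(axis=1)
        out[has_exact] = pv[idx]
    return out


def _empirical_variogram(px, py, pv, n_bins: int = 12):
    dx = px[:, None] - px[None, :]
    dy = py[:, None] - py[None, :]
    h = np.hypot(dx, dy)
    g = 0.5 * (pv[:, None] - pv[None, :]) ** 2
    iu = np.triu_indices(px.size, k=1)
    h, g = h[iu], g[iu]
    hmax = h.max()
    edges = np.linspace(0, hmax, n_bins + 1)
    centers, gammas = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (h > lo) & (h <= hi)
        if sel.sum() >= 2:
            centers.append(0.5 * (lo + hi))
            gammas.append(g[sel].mean())
    return np.asarray(centers), np.asarray(gammas)


def _fit_variogram(centers, gammas, model: str):
    """Least-squares fit of (nugget, sill/slope, range) for the variogram model."""
    if centers.size < 3:
        raise ValueError("too few variogram bins")
    if model == "linear":
        A = np.vstack([np.ones_like(centers), centers]).T
        (nugget, slope), *_ = np.linalg.lstsq(A, gammas, rcond=None)
        nugget = max(float(nugget), 0.0)
        slope = max(float(slope), 1e-12)
        return lambda h: nugget + slope * h
    if model == "spherical":
        rng = float(centers.max())
        hs = np.minimum(centers / rng, 1.0)
        basis = 1.5 * hs - 0.5 * hs**3
        A = np.vstack([np.ones_like(centers), basis]).T
        (nugget, sill), *_ = np.linalg.lstsq(A, gammas, rcond=None)
        nugget = max(float(nugget), 0.0)
        sill = max(float(sill), 1e-12)

        def gamma(h):
            hs = np.minimum(h / rng, 1.0)
            return nugget + sill * (1.5 * hs - 0.5 * hs**3)

        return gamma
    raise ValueError(f"unknown variogram model {model!r}")


def _ordinary_kriging(px, py, pv, qx, qy, variogram: str = "spherical") -> np.ndarray:
    n = px.size
    gamma = _fit_variogram(*_empirical_variogram(px, py, pv), model=variogram)
    d = np.hypot(px[:, None] - px[None, :], py[:, None] - py[None, :])
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = gamma(d)
    np.fill_diagonal(K[:n, :n], 0.0)
    K[n, :n] = 1.0
    K[:n, n] = 1.0
    K[n, n] = 0.0
    dq = np.hypot(px[None, :] - qx[:, None], py[None, :] - qy[:, None])
    rhs = np.empty((qx.size, n + 1))
    rhs[:, :n] = gamma(dq)
    rhs[:, :n][dq < 1e-12] = 0.0
    rhs[:, n] = 1.0
    w = np.linalg.solve(K, rhs.T).T  # (nq, n+1)
    return w[:, :n] @ pv


def interpolate(
    points,
    grid: GridSpec,
    method: str = "ordinary_kriging",
    params: dict | None = None,
) -> RasterLayer:
    """Interpolate scattered (lon, lat, value) points onto every grid cell.

    ``method``: ``ordinary_kriging`` (default; ``params['variogram']`` is
    ``spherical`` or ``linear``) or ``idw`` (``params['power']``, default 2).
    Kriging failures (singular system, degenerate variogram) fall back to IDW
    with a warning. Both are exact at data locations.
    """
    params = params or {}
    px, py, pv = (np.asarray(a, dtype=float) for a in points)
    if px.size == 0:
        raise ValueError("no points to interpolate")
    lon, lat = grid.cell_centers()
    qx, qy = lon.ravel(), lat.ravel()

    if method == "ordinary_kriging":
        if px.size < 3:
            raise ValueError("kriging needs at least 3 points")
        try:
            vals = _ordinary_kriging(px, py, pv, qx, qy,
                                     variogram=params.get("variogram", "spherical"))
            if not np.all(np.isfinite(vals)):
                raise np.linalg.LinAlgError("non-finite kriging weights")
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("kriging failed (%s); falling back to idw", exc)
            vals = _idw(px, py, pv, qx, qy, power=params.get("power", 2.0))
    elif method == "idw":
        vals = _idw(px, py, pv, qx, qy, power=params.get("power", 2.0))
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return RasterLayer(grid=grid, values=vals.reshape(grid.n_rows, grid.n_cols))


def sample_at_points(layer: RasterLayer, lon, lat) -> np.ndarray:
    """Value of the containing cell per point (nearest cell, no interpolation).

    Points outside the grid yield NaN.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    out = np.full(lon.shape, np.nan)
    inside = layer.grid.contains(lon, lat)
    row, col = layer.grid.rowcol(lon[inside], lat[inside])
    out[inside] = layer.values[row, col]
    return out


def write_ascii_grid(layer: RasterLayer, path, nodata: float = -9999.0) -> None:
    """Persist a raster as a plain-text ESRI ASCII grid."""
    g = layer.grid
    vals = np.where(np.isnan(layer.values), nodata, layer.values)
    header = (
        f"ncols {g.n_cols}\nnrows {g.n_rows}\n"
        f"xllcorner {g.west}\nyllcorner {g.south}\n"
        f"cellsize {g.cell}\nNODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path, semantics: str = "continuous") -> RasterLayer:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    vals = vals.reshape(n_rows, n_cols)
    vals[vals == header["nodata_value"]] = np.nan
    grid = GridSpec(
        west=header["xllcorner"],
        north=header["yllcorner"] + n_rows * header["cellsize"],
        cell=header["cellsize"],
        n_cols=n_cols,
        n_rows=n_rows,
    )
    return RasterLayer(grid=grid, values=vals, semantics=semantics)
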