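"""Georeferenced 2-D grids and raster I/O.

The package works entirely on geographic (WGS84 latitude/longitude) grids
with cell-centre coordinates.  Cell (0, 0) is the north-west corner and rows
increase southward.  Missing cells are represented internally as NaN; the
``nodata`` attribute records the sentinel used when the grid is written to
disk.

Rasters are read and written as GeoTIFF (via :mod:`tifffile`, using the
standard GeoTIFF georeferencing tags) or NetCDF (via :mod:`xarray`).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Grid2D",
    "DecadalClimatology",
    "aggregate",
    "read_grid",
    "write_grid",
    "GridIOError",
]

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113
_TAG_IMAGE_DESCRIPTION = 270

# Minimal GeoKey directory: geographic model, pixel-is-area, WGS84
_GEOKEYS_WGS84 = (
    1, 1, 0, 3,          # version, revision, minor, number of keys
    1024, 0, 1, 2,       # GTModelTypeGeoKey  = geographic
    1025, 0, 1, 1,       # GTRasterTypeGeoKey = PixelIsArea
    2048, 0, 1, 4326,    # GeographicTypeGeoKey = WGS84
)


class GridIOError(IOError):
    """Raised when a raster file cannot be read or lacks georeferencing."""


@dataclass
class Grid2D:
    """A single-variable raster on a regular geographic lattice.

    Parameters
    ----------
    values
        2-D float array; missing cells are NaN.
    lat_origin, lon_origin
        Cell-centre coordinates (degrees) of the north-west cell.
    resolution
        Cell size in degrees (> 0); square cells.
    nodata
        Sentinel written to disk for missing cells.
    units
        Free-text unit tag (``°C``, ``hPa``, ``m``, ``°C/km``, ``m/yr`` ...).
    """

    values: np.ndarray
    lat_origin: float
    lon_origin: float
    resolution: float
    nodata: float = float("nan")
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        # normalise the on-disk sentinel into NaN
        if not math.isnan(self.nodata):
            self.values = np.where(
                self.values == self.nodata, np.nan, self.values
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def lats(self) -> np.ndarray:
        """Cell-centre latitudes per row (decreasing southward)."""
        return self.lat_origin - self.resolution * np.arange(self.n_rows)

    def lons(self) -> np.ndarray:
        """Cell-centre longitudes per column (increasing eastward)."""
        return self.lon_origin + self.resolution * np.arange(self.n_cols)

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def same_geometry(self, other: "Grid2D", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.lat_origin - other.lat_origin) <= tol
            and abs(self.lon_origin - other.lon_origin) <= tol
            and abs(self.resolution - other.resolution) <= tol
        )

    def require_same_geometry(self, other: "Grid2D") -> None:
        if not self.same_geometry(other):
            raise ValueError(
                f"grid geometry mismatch: {self.shape}@"
                f"({self.lat_origin},{self.lon_origin},{self.resolution}) vs "
                f"{other.shape}@({other.lat_origin},{other.lon_origin},"
                f"{other.resolution})"
            )

    def like(self, values: np.ndarray, units: str | None = None) -> "Grid2D":
        """A new grid with the same geometry but different values."""
        return Grid2D(
            values=np.asarray(values, dtype=float),
            lat_origin=self.lat_origin,
            lon_origin=self.lon_origin,
            resolution=self.resolution,
            units=self.units if units is None else units,
        )

    def copy(self) -> "Grid2D":
        return self.like(self.values.copy())

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lat, lon) of the centre of cell (row, col)."""
        return (
            self.lat_origin - row * self.resolution,
            self.lon_origin + col * self.resolution,
        )

    def index_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Row/col of the cell whose footprint contains (lat, lon)."""
        row = int(round((self.lat_origin - lat) / self.resolution))
        col = int(round((lon - self.lon_origin) / self.resolution))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({lat}, {lon}) outside grid")
        return row, col


@dataclass
class DecadalClimatology:
    """Decadal-mean temperature and water-vapour-pressure fields.

    Temperature is mean annual temperature in °C averaged over a decade;
    vapour pressure is in hPa.  Both grids share geometry.
    """

    temperature: Grid2D
    vapour_pressure: Grid2D
    period_label: str = ""

    def __post_init__(self) -> None:
        self.temperature.require_same_geometry(self.vapour_pressure)
        vp = self.vapour_pressure.values
        if np.any(vp[np.isfinite(vp)] < 0):
            raise ValueError("vapour pressure must be non-negative")


def aggregate(fine: Grid2D, factor: int) -> Grid2D:
    """Block-average a grid to a coarser resolution.

    Each coarse cell is the mean of the finite fine cells in its
    ``factor x factor`` block; it is nodata only when the whole block is
    missing.  Trailing partial blocks are averaged over available cells.
    """
    if not isinstance(factor, (int, np.integer)) or factor <= 0:
        raise ValueError("aggregation factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return fine.copy()

    nr, nc = fine.shape
    out_r = -(-nr // factor)
    out_c = -(-nc // factor)
    padded = np.full((out_r * factor, out_c * factor), np.nan)
    padded[:nr, :nc] = fine.values
    blocks = padded.reshape(out_r, factor, out_c, factor)
    with np.errstate(invalid="ignore"):
        sums = np.nansum(blocks, axis=(1, 3))
        counts = np.isfinite(blocks).sum(axis=(1, 3))
    out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    # coarse cell centre = centre of its block
    shift = (factor - 1) / 2 * fine.resolution
    return Grid2D(
        values=out,
        lat_origin=fine.lat_origin - shift,
        lon_origin=fine.lon_origin + shift,
        resolution=fine.resolution * factor,
        units=fine.units,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_grid(grid: Grid2D, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a grid as GeoTIFF or NetCDF (inferred from extension)."""
    fmt = _resolve_format(path, format)
    if fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        _write_netcdf(grid, path)


def read_grid(path: str | os.PathLike, format: str | None = None) -> Grid2D:
    """Read a GeoTIFF or NetCDF raster into a :class:`Grid2D`."""
    if not os.path.exists(path):
        raise GridIOError(f"no such raster file: {path}")
    fmt = _resolve_format(path, format)
    try:
        if fmt == "geotiff":
            return _read_geotiff(path)
        return _read_netcdf(path)
    except GridIOError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise GridIOError(f"cannot read raster {path}: {exc}") from exc


def _resolve_format(path: str | os.PathLike, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt in ("geotiff", "tif", "tiff"):
            return "geotiff"
        if fmt in ("netcdf", "nc"):
            return "netcdf"
        raise ValueError(f"unknown raster format: {format}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".tif", ".tiff"):
        return "geotiff"
    if ext in (".nc", ".cdf", ".netcdf"):
        return "netcdf"
    raise ValueError(f"cannot infer raster format from extension: {path}")


def _write_geotiff(grid: Grid2D, path: str | os.PathLike) -> None:
    import tifffile

    nodata = -3.4e38  # sentinel well outside physical ranges
    data = np.where(np.isfinite(grid.values), grid.values, nodata)
    res = grid.resolution
    # GeoTIFF ties raster point (0,0) — the outer corner of the NW pixel —
    # to model space; our origin is that pixel's centre.
    west = grid.lon_origin - res / 2
    north = grid.lat_origin + res / 2
    desc = json.dumps({"units": grid.units})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (res, res, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, west, north, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(_GEOKEYS_WGS84), _GEOKEYS_WGS84),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]
    tifffile.imwrite(
        path,
        data.astype(np.float64),
        description=desc,
        extratags=extratags,
    )


def _read_geotiff(path: str | os.PathLike) -> Grid2D:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = {t.code: t.value for t in page.tags.values()}
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise GridIOError(f"file {path} lacks GeoTIFF georeferencing tags")
        data = page.asarray().astype(float)
        scale = tags[_TAG_MODEL_PIXEL_SCALE]
        tie = tags[_TAG_MODEL_TIEPOINT]
        res_x, res_y = float(scale[0]), float(scale[1])
        if not math.isclose(res_x, res_y, rel_tol=1e-9):
            raise GridIOError(f"non-square cells in {path} not supported")
        # tie point (i, j, k) -> (x, y, z): model coords of raster point i, j
        west = float(tie[3]) - float(tie[0]) * res_x
        north = float(tie[4]) + float(tie[1]) * res_y
        nodata = tags.get(_TAG_GDAL_NODATA)
        units = ""
        for tag in page.tags.getall(_TAG_IMAGE_DESCRIPTION, []):
            try:
                meta = json.loads(tag.value)
            except (json.JSONDecodeError, TypeError):
                continue
            if isinstance(meta, dict) and "units" in meta:
                units = meta["units"]
                break
        if nodata is not None:
            nd = float(nodata)
            data = np.where(np.isclose(data, nd, rtol=1e-6), np.nan, data)
    return Grid2D(
        values=data,
        lat_origin=north - res_y / 2,
        lon_origin=west + res_x / 2,
        resolution=res_x,
        units=units,
    )


def _write_netcdf(grid: Grid2D, path: str | os.PathLike) -> None:
    import xarray as xr

    da = xr.DataArray(
        grid.values,
        dims=("lat", "lon"),
        coords={"lat": grid.lats(), "lon": grid.lons()},
        attrs={"units": grid.units},
        name="value",
    )
    da.to_netcdf(path, engine="scipy")


def _read_netcdf(path: str | os.PathLike) -> Grid2D:
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        names = [n for n in ds.data_vars if {"lat", "lon"} <= set(ds[n].dims)]
        if not names:
            raise GridIOError(f"no lat/lon variable found in {path}")
        da = ds[names[0]].transpose("lat", "lon")
        lats = da["lat"].values
        lons = da["lon"].values
        if len(lats) < 1 or len(lons) < 1:
            raise GridIOError(f"empty raster in {path}")
        values = da.values.astype(float)
        units = str(da.attrs.get("units", ""))
    if len(lats) > 1 and lats[0] < lats[-1]:  # stored south-up; flip
        lats = lats[::-1]
        values = values[::-1]
    res = abs(lats[1] - lats[0]) if len(lats) > 1 else (
        abs(lons[1] - lons[0]) if len(lons) > 1 else 1.0
    )
    return Grid2D(
        values=values,
        lat_origin=float(lats[0]),
        lon_origin=float(lons[0]),
        resolution=float(res),
        units=units,
    )
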