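"""Raster data model for lat/lon environmental grids.

A :class:`Grid` is a regular, north-up longitude/latitude raster: row 0 is
the northernmost row, cells are half-open boxes
``[west + c*res, west + (c+1)*res) x [north - (r+1)*res, north - r*res)``
and cell centers sit at ``edge + res/2``.  Environmental descriptors live in
:class:`EnvLayer` objects (continuous values or categorical codes plus a
missing-value mask) grouped per time period into an :class:`EnvStack`.

Rasters are read and written as ESRI ASCII grids or single-band GeoTIFFs
(via tifffile, using the ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags).  Occurrence tables are plain CSV with columns
``species, longitude, latitude[, date]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Grid",
    "EnvLayer",
    "EnvStack",
    "ModelingExtent",
    "OccurrenceSet",
    "read_layer",
    "write_layer",
    "fill_missing",
    "mask_to_extent",
    "snap_and_dedupe",
    "read_occurrences",
    "write_occurrences",
]

logger = logging.getLogger(__name__)

NODATA = -9999.0

#: GeoTIFF tag codes used for georeferencing single-band north-up rasters.
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class Grid:
    """Regular lat/lon grid; row 0 is the northernmost row."""

    n_rows: int
    n_cols: int
    west: float
    south: float
    resolution: float = 0.1

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.resolution

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) center coordinate arrays of shape (n_rows, n_cols)."""
        res = self.resolution
        lon = self.west + (np.arange(self.n_cols) + 0.5) * res
        lat = self.north - (np.arange(self.n_rows) + 0.5) * res
        return np.meshgrid(lon, lat)

    def cell_of(self, lon, lat) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) using the half-open cell convention.

        A point exactly on an interior edge belongs to the cell east/south
        of the edge (the floor convention).
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.resolution).astype(int)
        row = np.floor((self.north - lat) / self.resolution).astype(int)
        # the north and west outer edges are inside the coverage
        row = np.where(np.isclose(lat, self.north), 0, row)
        col = np.where(np.isclose(lon, self.west) & (col == -1), 0, col)
        return row, col

    def contains(self, lon, lat) -> np.ndarray:
        row, col = self.cell_of(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def approx_equal(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.west - other.west) <= tol
            and abs(self.south - other.south) <= tol
            and abs(self.resolution - other.resolution) <= tol
        )


@dataclass
class EnvLayer:
    """One environmental descriptor on a grid.

    ``mask`` is True where the value is missing or excluded from the
    modeling extent; such cells never enter sums, samples or model fits.
    """

    name: str
    grid: Grid
    values: np.ndarray
    mask: np.ndarray
    kind: str = "continuous"  # "continuous" | "categorical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise ValueError(f"layer {self.name!r}: array shape does not match grid")
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValueError(f"layer {self.name!r}: non-finite values outside mask")

    def copy(self) -> "EnvLayer":
        return EnvLayer(self.name, self.grid, self.values.copy(), self.mask.copy(), self.kind)


@dataclass
class EnvStack:
    """Named layers on a shared grid for one time period."""

    grid: Grid
    period: str
    layers: dict[str, EnvLayer] = field(default_factory=dict)

    def add(self, layer: EnvLayer) -> None:
        if layer.name in self.layers:
            raise ValueError(f"duplicate layer name {layer.name!r}")
        if not layer.grid.approx_equal(self.grid):
            raise ValueError(f"layer {layer.name!r} grid does not match stack grid")
        self.layers[layer.name] = layer

    def __getitem__(self, name: str) -> EnvLayer:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where every layer has a value (usable cells)."""
        ok = np.ones(self.grid.shape, dtype=bool)
        for layer in self.layers.values():
            ok &= ~layer.mask
        return ok

    def feature_matrix(self, names: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack layer values into an (n_valid_cells, n_layers) matrix.

        Returns (X, flat_cell_index) over cells valid in every layer.
        """
        names = list(names) if names is not None else self.names
        ok = self.valid_mask()
        idx = np.flatnonzero(ok.ravel())
        X = np.column_stack([self.layers[n].values.ravel()[idx] for n in names])
        return X, idx

    def subset(self, names: Sequence[str]) -> "EnvStack":
        out = EnvStack(self.grid, self.period)
        for n in names:
            out.add(self.layers[n])
        return out

    def copy(self) -> "EnvStack":
        out = EnvStack(self.grid, self.period)
        for layer in self.layers.values():
            out.add(layer.copy())
        return out


@dataclass(frozen=True)
class ModelingExtent:
    """Geographic bounding box plus a maximal depth (meters, positive down)."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    max_depth: float

    def __post_init__(self) -> None:
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("degenerate bounding box")
        if self.max_depth <= 0:
            raise ValueError("max_depth must be positive (meters, positive down)")


@dataclass
class OccurrenceSet:
    """Presence-only records snapped to grid cells, one per cell."""

    species: str
    grid: Grid
    lon: np.ndarray
    lat: np.ndarray
    rows: np.ndarray
    cols: np.ndarray

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def flat_cells(self) -> np.ndarray:
        return self.rows * self.grid.n_cols + self.cols


# ---------------------------------------------------------------------------
# raster I/O


def _read_ascii(path: Path) -> tuple[Grid, np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0].lower() not in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh, dtype=float)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    nodata = header.get("nodata_value", NODATA)
    grid = Grid(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        west=header["xllcorner"],
        south=header["yllcorner"],
        resolution=header["cellsize"],
    )
    data = np.atleast_2d(data)
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} does not match header {grid.shape}")
    return grid, data, nodata


def _read_geotiff(path: Path) -> tuple[Grid, np.ndarray, float]:
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        data = np.asarray(page.asarray(), dtype=float)
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tie = tags[_TAG_TIEPOINT].value
        west, north = tie[3], tie[4]
        nodata = NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
    if data.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    if not np.isclose(sx, sy):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) are not supported")
    n_rows, n_cols = data.shape
    grid = Grid(n_rows=n_rows, n_cols=n_cols, west=west, south=north - n_rows * sx, resolution=sx)
    return grid, data, nodata


def read_layer(path: str | Path, name: str, kind: str = "continuous",
               grid: Grid | None = None) -> EnvLayer:
    """Read a single-band raster (ESRI ASCII or GeoTIFF) into an EnvLayer.

    Depth/bathymetry layers stored as negative elevation are negated on
    read when ``name`` contains "depth" and all finite values are <= 0.
    If ``grid`` is given, the file's grid must match it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        file_grid, data, nodata = _read_geotiff(path)
    else:
        file_grid, data, nodata = _read_ascii(path)
    if grid is not None and not file_grid.approx_equal(grid):
        raise ValueError(f"{path}: grid does not match the expected grid")
    mask = np.isclose(data, nodata) | ~np.isfinite(data)
    values = np.where(mask, 0.0, data)
    if "depth" in name.lower() and np.all(values[~mask] <= 0) and np.any(values[~mask] < 0):
        logger.info("layer %r: negative-elevation input negated to positive-down depth", name)
        values = np.where(mask, 0.0, -values)
    return EnvLayer(name=name, grid=file_grid, values=values, mask=mask, kind=kind)


def write_layer(layer: EnvLayer, path: str | Path) -> Path:
    """Write a layer as ESRI ASCII (default) or GeoTIFF (by .tif suffix)."""
    path = Path(path)
    g = layer.grid
    data = np.where(layer.mask, NODATA, layer.values)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        extratags = [
            (_TAG_PIXEL_SCALE, "d", 3, (g.resolution, g.resolution, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.west, g.north, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(NODATA)),
        ]
        tifffile.imwrite(str(path), data.astype(np.float64), extratags=extratags)
    else:
        with open(path, "w") as fh:
            fh.write(f"ncols {g.n_cols}\n")
            fh.write(f"nrows {g.n_rows}\n")
            fh.write(f"xllcorner {g.west:.10g}\n")
            fh.write(f"yllcorner {g.south:.10g}\n")
            fh.write(f"cellsize {g.resolution:.10g}\n")
            fh.write(f"NODATA_value {NODATA:.10g}\n")
            for row in data:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# operations


def fill_missing(layer: EnvLayer) -> EnvLayer:
    """Fill masked cells with the value of the nearest non-missing cell.

    Distance is Euclidean in cell units; ties are broken by row-major order
    of the candidate source cells.  Observed cells are never altered, and
    the operation is idempotent.
    """
    if not np.any(~layer.mask):
        raise ValueError(f"layer {layer.name!r} is fully missing; nothing to interpolate")
    if not np.any(layer.mask):
        return layer.copy()
    obs_r, obs_c = np.nonzero(~layer.mask)
    mis_r, mis_c = np.nonzero(layer.mask)
    seeds = np.column_stack([obs_r, obs_c]).astype(float)
    targets = np.column_stack([mis_r, mis_c]).astype(float)
    tree = cKDTree(seeds)
    dist, nearest = tree.query(targets)
    # exact-tie refinement: among equidistant seeds take the row-major first
    # (seeds are already in row-major order, so the minimum index wins)
    for i, (pt, d) in enumerate(zip(targets, dist)):
        cand = tree.query_ball_point(pt, r=d + 1e-9)
        if len(cand) > 1:
            nearest[i] = min(cand)
    values = layer.values.copy()
    values[mis_r, mis_c] = layer.values[obs_r[nearest], obs_c[nearest]]
    return EnvLayer(layer.name, layer.grid, values,
                    np.zeros(layer.grid.shape, dtype=bool), layer.kind)


def mask_to_extent(stack: EnvStack, extent: ModelingExtent,
                   depth_layer_name: str = "depth") -> EnvStack:
    """Restrict a stack to a geographic box and a maximal depth.

    Cells outside the lat/lon box, deeper than ``extent.max_depth`` or
    missing in the depth layer are masked in every layer of the returned
    stack.  Masking only grows: a cell masked on input stays masked.
    """
    if depth_layer_name not in stack:
        raise ValueError(f"depth layer {depth_layer_name!r} not present in stack")
    lon, lat = stack.grid.cell_centers()
    inside = (
        (lat >= extent.lat_min) & (lat <= extent.lat_max)
        & (lon >= extent.lon_min) & (lon <= extent.lon_max)
    )
    depth = stack[depth_layer_name]
    inside &= ~depth.mask & (depth.values <= extent.max_depth)
    if not np.any(inside):
        raise ValueError("empty modeling area: no cell satisfies the extent and depth limits")
    out = EnvStack(stack.grid, stack.period)
    for layer in stack.layers.values():
        out.add(EnvLayer(layer.name, layer.grid, layer.values.copy(),
                         layer.mask | ~inside, layer.kind))
    return out


def snap_and_dedupe(records: pd.DataFrame | Iterable[tuple[float, float]],
                    grid: Grid, species: str = "species") -> OccurrenceSet:
    """Snap occurrence records to grid cells and drop within-cell duplicates.

    Records outside the grid coverage are dropped with a logged count.  For
    each occupied cell the first record in input order is retained; the
    result is idempotent under re-application.
    """
    if isinstance(records, pd.DataFrame):
        lon = records["longitude"].to_numpy(dtype=float)
        lat = records["latitude"].to_numpy(dtype=float)
        if "species" in records.columns and len(records) and species == "species":
            species = str(records["species"].iloc[0])
    else:
        pts = np.asarray(list(records), dtype=float).reshape(-1, 2)
        lon, lat = pts[:, 0], pts[:, 1]
    keep = grid.contains(lon, lat)
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        logger.info("snap_and_dedupe: dropped %d record(s) outside grid coverage", n_dropped)
    lon, lat = lon[keep], lat[keep]
    if lon.size == 0:
        raise ValueError("no occurrence records fall within the grid coverage")
    rows, cols = grid.cell_of(lon, lat)
    flat = rows * grid.n_cols + cols
    _, first = np.unique(flat, return_index=True)
    first = np.sort(first)
    return OccurrenceSet(species=species, grid=grid, lon=lon[first], lat=lat[first],
                         rows=rows[first], cols=cols[first])


# ---------------------------------------------------------------------------
# occurrence CSV I/O


def read_occurrences(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"species", "longitude", "latitude"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: occurrence CSV missing columns {sorted(missing)}")
    return df


def write_occurrences(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
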