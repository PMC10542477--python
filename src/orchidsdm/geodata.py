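"""Shared grid/raster/vector data model and spatial primitives.

Every layer in an analysis lives on a single projected equal-area grid
(1-km cells by default), indexed row-major from the top-left corner.
Cell (row, col) covers the half-open box
``[origin_x + col*cs, origin_x + (col+1)*cs)`` horizontally and the
corresponding half-open interval measured downwards from ``origin_y``.
Area arithmetic is therefore exact: one cell is ``cell_size**2`` m².

Rasters are written and read as single-band GeoTIFFs (tifffile with the
baseline GeoTIFF georeferencing tags); vectors travel as GeoJSON in the
grid CRS.  No reprojection is ever performed: a CRS or cell-size mismatch
is an error, never a silent resample.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger("orchidsdm")

# GeoTIFF / GDAL tag codes used for round-tripping grid metadata.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class GridAlignmentError(ValueError):
    """A layer does not share the session grid (CRS, cell size or extent)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis grid.

    Coordinates are projected metres in an equal-area CRS supplied by the
    caller (``crs_id`` is an opaque identifier; layers only need to agree).
    """

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    crs_id: str = "local-equal-area"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every cell center, each shaped (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def point_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map a point to its (row, col); half-open cell intervals.

        Points outside the grid raise ``ValueError``.
        """
        col = math.floor((x - self.origin_x) / self.cell_size)
        row = math.floor((self.origin_y - y) / self.cell_size)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def points_to_cells(self, xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cols = np.floor((np.asarray(xs) - self.origin_x) / self.cell_size).astype(int)
        rows = np.floor((self.origin_y - np.asarray(ys)) / self.cell_size).astype(int)
        bad = (rows < 0) | (rows >= self.n_rows) | (cols < 0) | (cols >= self.n_cols)
        if bad.any():
            raise ValueError(f"{int(bad.sum())} point(s) outside grid extent")
        return rows, cols

    def bbox(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the full grid."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )


@dataclass
class Raster:
    """A single-band gridded layer with a validity mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.mask is None:
            self.mask = np.ones(self.grid.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.all(np.isfinite(self.values[self.mask])):
                raise ValueError("non-finite values inside the valid mask")

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None,
                  categorical: bool | None = None) -> "Raster":
        return Raster(
            self.grid,
            values,
            self.mask.copy() if mask is None else mask,
            self.categorical if categorical is None else categorical,
        )

    def masked_values(self) -> np.ndarray:
        """Values at valid cells, as a 1-D array."""
        return self.values[self.mask]


@dataclass
class FeatureSet:
    """Typed geometries (grid CRS) with a uniform per-feature attribute table."""

    geometries: list[BaseGeometry]
    attributes: list[dict] = field(default_factory=list)
    crs_id: str = "local-equal-area"

    def __post_init__(self) -> None:
        if self.attributes and len(self.attributes) != len(self.geometries):
            raise ValueError("attributes length must match geometries")
        if not self.attributes:
            self.attributes = [{} for _ in self.geometries]
        keysets = {frozenset(a) for a in self.attributes}
        if len(keysets) > 1:
            raise ValueError("attribute keys must be uniform across features")

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class CountyTable:
    """Administrative polygons used for zonal statistics.

    county_ids are unique; ``area_km2`` is the polygon area (km²), which for
    a Voronoi partition of the grid equals the zonal cell count at 1 km.
    """

    county_ids: list[int]
    names: list[str]
    geometries: list[BaseGeometry]
    crs_id: str = "local-equal-area"

    def __post_init__(self) -> None:
        if len(set(self.county_ids)) != len(self.county_ids):
            raise ValueError("county_ids must be unique")
        if not (len(self.county_ids) == len(self.names) == len(self.geometries)):
            raise ValueError("ragged county table")
        for g in self.geometries:
            if g.area <= 0:
                raise ValueError("county polygons must have positive area")

    def __len__(self) -> int:
        return len(self.county_ids)

    @property
    def area_km2(self) -> list[float]:
        return [g.area / 1e6 for g in self.geometries]


# ---------------------------------------------------------------------------
# Raster I/O (single-band GeoTIFF)
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a single-band GeoTIFF; nodata cells carry the grid sentinel."""
    path = Path(path)
    g = raster.grid
    values = np.array(raster.values, copy=True)
    if np.issubdtype(values.dtype, np.floating):
        values[~raster.mask] = g.nodata
        nodata_repr = repr(float(g.nodata))
    else:
        # integer rasters (e.g. class codes) use 255 as nodata
        values[~raster.mask] = 255
        nodata_repr = "255"
    desc = json.dumps(
        {
            "crs_id": g.crs_id,
            "nodata": g.nodata,
            "categorical": raster.categorical,
        }
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.cell_size, g.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_repr),
    ]
    tifffile.imwrite(path, values, description=desc, extratags=extratags)
    return path


def read_raster(path: str | Path, session_grid: GridSpec | None = None) -> Raster:
    """Read a GeoTIFF written by :func:`write_raster`.

    If ``session_grid`` is given, the file must match it exactly (CRS and
    cell size); a mismatch raises :class:`GridAlignmentError` rather than
    resampling silently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        meta = json.loads(page.description) if page.description else {}
    cell_size = float(scale[0])
    origin_x, origin_y = float(tiepoint[3]), float(tiepoint[4])
    crs_id = meta.get("crs_id", "unknown")
    nodata = float(meta.get("nodata", -9999.0))
    grid = GridSpec(
        origin_x=origin_x,
        origin_y=origin_y,
        n_rows=values.shape[0],
        n_cols=values.shape[1],
        cell_size=cell_size,
        crs_id=crs_id,
        nodata=nodata,
    )
    if session_grid is not None:
        if crs_id != session_grid.crs_id:
            raise GridAlignmentError(
                f"raster CRS {crs_id!r} != session CRS {session_grid.crs_id!r}; "
                "reproject externally, this package never reprojects"
            )
        if cell_size != session_grid.cell_size:
            raise GridAlignmentError(
                f"raster cell size {cell_size} m != session cell size "
                f"{session_grid.cell_size} m"
            )
    if np.issubdtype(values.dtype, np.floating):
        mask = values != nodata
    else:
        mask = values != 255
    return Raster(grid, values, mask, categorical=bool(meta.get("categorical", False)))


# ---------------------------------------------------------------------------
# Vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def write_features(features: FeatureSet, path: str | Path) -> Path:
    path = Path(path)
    fc = {
        "type": "FeatureCollection",
        "crs_id": features.crs_id,
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": a}
            for g, a in zip(features.geometries, features.attributes)
        ],
    }
    path.write_text(json.dumps(fc))
    return path


def read_features(path: str | Path) -> FeatureSet:
    fc = json.loads(Path(path).read_text())
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    attrs = [f.get("properties") or {} for f in fc["features"]]
    return FeatureSet(geoms, attrs, crs_id=fc.get("crs_id", "unknown"))


def write_counties(counties: CountyTable, path: str | Path) -> Path:
    fs = FeatureSet(
        counties.geometries,
        [
            {"county_id": cid, "name": name}
            for cid, name in zip(counties.county_ids, counties.names)
        ],
        crs_id=counties.crs_id,
    )
    return write_features(fs, path)


def read_counties(path: str | Path) -> CountyTable:
    fs = read_features(path)
    return CountyTable(
        [a["county_id"] for a in fs.attributes],
        [a["name"] for a in fs.attributes],
        fs.geometries,
        crs_id=fs.crs_id,
    )


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_to_grid(
    raster: Raster,
    target: GridSpec,
    method: Literal["nearest", "mean"] = "nearest",
) -> Raster:
    """Resample a raster onto the session grid.

    Source and target must share a CRS.  ``mean`` aggregates source cells
    whose centers fall inside each target cell and is refused for
    categorical layers; ``nearest`` picks the source cell containing the
    target cell center.
    """
    src = raster.grid
    if src.crs_id != target.crs_id:
        raise GridAlignmentError(
            f"source CRS {src.crs_id!r} != target CRS {target.crs_id!r}"
        )
    if method not in ("nearest", "mean"):
        raise ValueError(f"unknown method {method!r}")
    if method == "mean" and raster.categorical:
        raise ValueError("mean resampling is undefined for categorical layers")
    if src == target:
        return raster.copy_with(raster.values.copy())

    if method == "nearest":
        tx, ty = target.cell_centers()
        cols = np.floor((tx - src.origin_x) / src.cell_size).astype(int)
        rows = np.floor((src.origin_y - ty) / src.cell_size).astype(int)
        inside = (
            (rows >= 0) & (rows < src.n_rows) & (cols >= 0) & (cols < src.n_cols)
        )
        rows_c = np.clip(rows, 0, src.n_rows - 1)
        cols_c = np.clip(cols, 0, src.n_cols - 1)
        values = raster.values[rows_c, cols_c]
        mask = inside & raster.mask[rows_c, cols_c]
        return Raster(target, values, mask, categorical=raster.categorical)

    # mean: bin source cell centers into target cells
    sx, sy = src.cell_centers()
    tcols = np.floor((sx - target.origin_x) / target.cell_size).astype(int)
    trows = np.floor((target.origin_y - sy) / target.cell_size).astype(int)
    ok = (
        (trows >= 0)
        & (trows < target.n_rows)
        & (tcols >= 0)
        & (tcols < target.n_cols)
        & raster.mask
    )
    flat = trows[ok] * target.n_cols + tcols[ok]
    sums = np.bincount(flat, weights=raster.values[ok].astype(float),
                       minlength=target.n_cells)
    counts = np.bincount(flat, minlength=target.n_cells)
    with np.errstate(invalid="ignore"):
        means = sums / counts
    values = means.reshape(target.shape)
    mask = (counts > 0).reshape(target.shape)
    values[~mask] = target.nodata
    return Raster(target, values, mask)


# ---------------------------------------------------------------------------
# Distance transform and zonal statistics
# ---------------------------------------------------------------------------

def distance_to_features(grid: GridSpec, features: FeatureSet) -> Raster:
    """Euclidean distance (m) from each cell center to the nearest feature."""
    if len(features) == 0:
        raise ValueError("empty FeatureSet: distance transform undefined")
    xs, ys = grid.cell_centers()
    points = shapely.points(xs.ravel(), ys.ravel())
    union = shapely.union_all(np.asarray(features.geometries, dtype=object))
    d = shapely.distance(points, union)
    return Raster(grid, d.reshape(grid.shape))


def county_membership(grid: GridSpec, counties: CountyTable) -> np.ndarray:
    """Per-cell county_id (or -1 when uncovered), by center containment.

    A center on a shared boundary is assigned to the county with the lowest
    county_id (counties are scanned in ascending id order).
    """
    xs, ys = grid.cell_centers()
    points = shapely.points(xs.ravel(), ys.ravel())
    membership = np.full(grid.n_cells, -1, dtype=int)
    order = np.argsort(counties.county_ids)
    for i in order:
        geom = counties.geometries[i]
        shapely.prepare(geom)
        unassigned = membership == -1
        if not unassigned.any():
            break
        hit = shapely.covers(geom, points[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        membership[idx] = counties.county_ids[i]
    return membership.reshape(grid.shape)


def zonal_area(binary: Raster, counties: CountyTable) -> dict[int, float]:
    """km² of value-1 cells per county (cell-center membership)."""
    vals = binary.values
    on_mask = vals[binary.mask]
    if not np.isin(on_mask, (0, 1)).all():
        raise ValueError("zonal_area requires a 0/1 raster on the valid mask")
    membership = county_membership(binary.grid, counties)
    suitable = (vals == 1) & binary.mask
    uncovered = int((suitable & (membership == -1)).sum())
    if uncovered:
        logger.warning("%d suitable cell(s) not covered by any county", uncovered)
    cell_area = binary.grid.cell_area_km2
    out = {}
    for cid in counties.county_ids:
        out[cid] = float((suitable & (membership == cid)).sum()) * cell_area
    return out
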