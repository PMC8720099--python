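"""Gridded environmental data: containers, GeoTIFF I/O, simple indices, plot extraction.

The grid convention is row-major with the origin at the *outer* corner of the
first (top-left) cell and y decreasing downwards, i.e. cell ``(row, col)``
covers the half-open world rectangle

    x in [x0 + col*cs, x0 + (col+1)*cs)
    y in (y0 - (row+1)*cs, y0 - row*cs]

so a point lying exactly on a shared edge belongs to the cell with the larger
index.  Cells are square; rectangular cells are rejected on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile
from shapely.geometry import Point, Polygon

__all__ = [
    "RasterGrid",
    "PlotGeometry",
    "read_raster",
    "write_raster",
    "ndvi",
    "rbvi",
    "tpi",
    "extract_plot_values",
]

# private TIFF tag codes used for georeferencing (GeoTIFF convention)
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A georeferenced 2-D numeric grid with square cells.

    Parameters
    ----------
    values
        2-D float array; missing cells hold ``nodata``.
    origin
        ``(x, y)`` of the outer corner of cell ``(0, 0)`` (top-left).
    cell_size
        Cell edge length in metres (> 0, square cells).
    nodata
        Sentinel marking missing cells.
    crs_tag
        Opaque coordinate-reference identifier; carried through I/O.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 30.0
    nodata: float = DEFAULT_NODATA
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        bad = ~np.isfinite(self.values) & ~np.isnan(self.values)
        if np.any(bad):
            raise ValueError("raster values must be finite, NaN or the nodata sentinel")

    # -- shape / masking ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells that carry data."""
        with np.errstate(invalid="ignore"):
            return np.isfinite(self.values) & (self.values != self.nodata)

    def finite_values(self) -> np.ndarray:
        """1-D array of all data-carrying cell values."""
        return self.values[self.valid_mask()]

    # -- coordinate mapping ------------------------------------------------
    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Map world coordinates to the containing ``(row, col)``.

        Raises ``ValueError`` for points outside the grid extent.
        """
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        nr, nc = self.shape
        # a point exactly on the far edge belongs to the last cell
        if col == nc and np.isclose(x, x0 + nc * self.cell_size):
            col = nc - 1
        if row == nr and np.isclose(y, y0 - nr * self.cell_size):
            row = nr - 1
        if not (0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"point ({x}, {y}) lies outside the raster extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 - (row + 0.5) * self.cell_size,
        )

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid."""
        x0, y0 = self.origin
        nr, nc = self.shape
        return (x0, y0 - nr * self.cell_size, x0 + nc * self.cell_size, y0)

    def contains_point(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent()
        return xmin <= x <= xmax and ymin <= y <= ymax

    def with_values(self, values: np.ndarray, nodata: float | None = None) -> "RasterGrid":
        """A new grid sharing this grid's georeferencing."""
        return RasterGrid(
            values=values,
            origin=self.origin,
            cell_size=self.cell_size,
            nodata=self.nodata if nodata is None else nodata,
            crs_tag=self.crs_tag,
        )

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
        )


@dataclass
class PlotGeometry:
    """A sampling plot: a point or a simple polygon in raster coordinates."""

    plot_id: str
    geometry: tuple[float, float] | Sequence[tuple[float, float]]
    elevation_m: float | None = None

    def __post_init__(self) -> None:
        g = self.geometry
        if self.is_point:
            if not all(np.isfinite(g)):
                raise ValueError(f"plot {self.plot_id}: non-finite coordinates")
        else:
            coords = [tuple(map(float, v)) for v in g]
            if len(coords) < 3:
                raise ValueError(f"plot {self.plot_id}: polygon needs >= 3 vertices")
            if not all(np.isfinite(c) for xy in coords for c in xy):
                raise ValueError(f"plot {self.plot_id}: non-finite coordinates")
            poly = Polygon(coords)
            if not poly.is_valid:
                raise ValueError(f"plot {self.plot_id}: invalid (self-intersecting?) polygon")
            self.geometry = coords

    @property
    def is_point(self) -> bool:
        g = self.geometry
        return len(g) == 2 and np.isscalar(g[0])

    def as_shapely(self):
        if self.is_point:
            return Point(*self.geometry)
        return Polygon(self.geometry)

    def centroid(self) -> tuple[float, float]:
        if self.is_point:
            return tuple(map(float, self.geometry))
        c = Polygon(self.geometry).centroid
        return (c.x, c.y)


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile backend)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path) -> None:
    """Write a :class:`RasterGrid` to a single-band float GeoTIFF.

    Georeferencing is stored in the standard ModelPixelScale / ModelTiepoint
    tags; the nodata sentinel goes into the GDAL_NODATA tag and the crs tag
    into the image description.  Round trips are lossless.
    """
    sx = sy = float(grid.cell_size)
    x0, y0 = map(float, grid.origin)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (sx, sy, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)),
    ]
    tifffile.imwrite(
        str(path),
        grid.values.astype(np.float64),
        description=json.dumps({"crs_tag": grid.crs_tag}),
        extratags=extratags,
    )


def read_raster(path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or
    compatible).  Rejects rasters with rectangular (non-square) cells."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not np.isclose(sx, sy):
            raise ValueError(
                f"{path}: rectangular cells ({sx} x {sy}) are not supported; "
                "cells must be square"
            )
        tp = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> world (x, y, z); we require (0, 0)
        x0 = tp[3] - tp[0] * sx
        y0 = tp[4] + tp[1] * sy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        crs_tag = "local"
        desc = tags.get(270)
        if desc is not None:
            try:
                crs_tag = json.loads(desc.value).get("crs_tag", "local")
            except (json.JSONDecodeError, AttributeError):
                pass
    return RasterGrid(values=values, origin=(x0, y0), cell_size=float(sx),
                      nodata=nodata, crs_tag=crs_tag)


# ---------------------------------------------------------------------------
# Simple band / terrain indices
# ---------------------------------------------------------------------------

def _check_same_grid(a: RasterGrid, b: RasterGrid) -> None:
    if not a.same_grid(b):
        raise ValueError("input rasters are not co-registered (shape/origin/cell size differ)")


def _normalized_difference(a: RasterGrid, b: RasterGrid) -> RasterGrid:
    _check_same_grid(a, b)
    mask = a.valid_mask() & b.valid_mask()
    denom = a.values + b.values
    out = np.full(a.shape, a.nodata)
    ok = mask & (denom != 0)
    out[ok] = (a.values[ok] - b.values[ok]) / denom[ok]
    return a.with_values(out)


def ndvi(nir: RasterGrid, red: RasterGrid) -> RasterGrid:
    """Normalized difference vegetation index, (NIR - red)/(NIR + red)."""
    return _normalized_difference(nir, red)


def rbvi(red: RasterGrid, blue: RasterGrid) -> RasterGrid:
    """Red-blue normalized difference index, (red - blue)/(red + blue)."""
    return _normalized_difference(red, blue)


def _window_sum(a: np.ndarray, radius: int) -> np.ndarray:
    """Exact truncated moving-window sum via an integral image."""
    nr, nc = a.shape
    integral = np.zeros((nr + 1, nc + 1))
    integral[1:, 1:] = np.cumsum(np.cumsum(a, axis=0), axis=1)
    r = np.arange(nr)
    c = np.arange(nc)
    r0 = np.clip(r - radius, 0, nr)
    r1 = np.clip(r + radius + 1, 0, nr)
    c0 = np.clip(c - radius, 0, nc)
    c1 = np.clip(c + radius + 1, 0, nc)
    return (
        integral[np.ix_(r1, c1)]
        - integral[np.ix_(r0, c1)]
        - integral[np.ix_(r1, c0)]
        + integral[np.ix_(r0, c0)]
    )


def tpi(dem: RasterGrid, window_radius: int = 1) -> RasterGrid:
    """Topographic position index: elevation minus the mean elevation of the
    surrounding square window (side ``2*window_radius + 1``), centre excluded.

    Boundary cells use the truncated window; nodata cells are excluded from
    the neighbourhood mean and propagate as nodata in the output.
    Positive values mark ridges, negative values valleys.
    """
    if window_radius < 1:
        raise ValueError("window_radius must be >= 1")
    nr, nc = dem.shape
    side = 2 * window_radius + 1
    if side > nr or side > nc:
        raise ValueError(f"window side {side} exceeds grid shape {dem.shape}")
    mask = dem.valid_mask()
    vals = np.where(mask, dem.values, 0.0)
    wsum = _window_sum(vals, window_radius)
    wcnt = _window_sum(mask.astype(float), window_radius)
    # exclude the centre cell from its own neighbourhood
    nsum = wsum - vals
    ncnt = np.rint(wcnt).astype(int) - mask.astype(int)
    out = np.full(dem.shape, dem.nodata)
    ok = mask & (ncnt > 0)
    out[ok] = dem.values[ok] - nsum[ok] / ncnt[ok]
    return dem.with_values(out)


# ---------------------------------------------------------------------------
# Plot extraction
# ---------------------------------------------------------------------------

def _polygon_cells(grid: RasterGrid, poly: Polygon) -> list[tuple[int, int]]:
    """Cells whose centre lies inside the polygon (center-containment rule)."""
    xmin, ymin, xmax, ymax = poly.bounds
    x0, y0 = grid.origin
    cs = grid.cell_size
    nr, nc = grid.shape
    c_lo = max(0, int(np.floor((xmin - x0) / cs)) - 1)
    c_hi = min(nc - 1, int(np.floor((xmax - x0) / cs)) + 1)
    r_lo = max(0, int(np.floor((y0 - ymax) / cs)) - 1)
    r_hi = min(nr - 1, int(np.floor((y0 - ymin) / cs)) + 1)
    cells = []
    for r in range(r_lo, r_hi + 1):
        for c in range(c_lo, c_hi + 1):
            if poly.contains(Point(*grid.cell_center(r, c))):
                cells.append((r, c))
    return cells


def extract_plot_values(grid: RasterGrid, plot: PlotGeometry,
                        reducer: str = "mean") -> float:
    """Per-plot value of an environmental raster.

    Points return the value of the containing cell.  Polygons are reduced
    over all cells whose centre falls inside (``reducer='mean'``, the
    default) or evaluated at the cell containing the polygon centroid
    (``reducer='center'``).  Nodata cells are excluded; a plot that touches
    only nodata raises.
    """
    if reducer not in ("mean", "center"):
        raise ValueError(f"unknown reducer {reducer!r}")
    mask = grid.valid_mask()
    if plot.is_point or reducer == "center":
        x, y = plot.centroid()
        if not grid.contains_point(x, y):
            raise ValueError(f"plot {plot.plot_id} lies outside the raster extent")
        r, c = grid.world_to_cell(x, y)
        if not mask[r, c]:
            raise ValueError(f"plot {plot.plot_id} falls on a nodata cell")
        return float(grid.values[r, c])
    cells = _polygon_cells(grid, plot.as_shapely())
    if not cells:
        # tiny polygon between cell centres: fall back to the centroid cell
        x, y = plot.centroid()
        if not grid.contains_point(x, y):
            raise ValueError(f"plot {plot.plot_id} lies outside the raster extent")
        cells = [grid.world_to_cell(x, y)]
    vals = [grid.values[r, c] for r, c in cells if mask[r, c]]
    if not vals:
        raise ValueError(f"plot {plot.plot_id}: all intersected cells are nodata")
    return float(np.mean(vals))


def load_plots_csv(path) -> list[PlotGeometry]:
    """Read plots from a CSV with columns ``plot_id, x, y[, elevation_m]`` or
    a WKT geometry column named ``geometry``."""
    import pandas as pd
    from shapely import wkt as shapely_wkt

    df = pd.read_csv(path)
    plots: list[PlotGeometry] = []
    for _, row in df.iterrows():
        pid = str(row["plot_id"])
        elev = float(row["elevation_m"]) if "elevation_m" in df.columns else None
        if "geometry" in df.columns:
            geom = shapely_wkt.loads(row["geometry"])
            if geom.geom_type == "Point":
                plots.append(PlotGeometry(pid, (geom.x, geom.y), elev))
            else:
                plots.append(PlotGeometry(pid, list(geom.exterior.coords), elev))
        else:
            plots.append(PlotGeometry(pid, (float(row["x"]), float(row["y"])), elev))
    return plots
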