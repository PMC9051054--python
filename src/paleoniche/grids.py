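"""Raster data model, GeoTIFF I/O and per-cell area computation.

All analysis rasters live on a single equal-area grid (default an
EPSG:3035-style Lambert azimuthal equal-area grid with cell sizes in
metres), so that the suitable area ``A`` in the carrying-capacity formula
``P = D-bar x A`` reduces to a cell count times a constant.  Geographic
(degree) grids are supported only for area computation on the sphere.

Grid convention
---------------
Row-major, 0-based indices.  ``origin`` is the *top-left corner* of the
raster; the centre of cell ``(row, col)`` sits at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size

i.e. rows advance southward, matching the GeoTIFF/top-left raster
convention.  Nodata cells are excluded from every statistic; they are
never treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = [
    "RasterGrid",
    "Layer",
    "Mask",
    "GridConformanceError",
    "cell_areas",
    "mask_area_km2",
    "read_raster",
    "write_raster",
    "read_mask",
    "write_mask",
    "EARTH_RADIUS_KM",
]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_MODEL_TYPE = 1024      # 1 = projected, 2 = geographic
_KEY_GEOGRAPHIC_CS = 2048
_KEY_PROJECTED_CS = 3072


class GridConformanceError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass(frozen=True)
class RasterGrid:
    """Geometry and georeferencing shared by a stack of layers."""

    n_rows: int
    n_cols: int
    cell_size: float  # metres for projected grids, degrees for geographic
    origin: tuple[float, float]  # top-left corner (x, y) / (lon, lat)
    crs_id: str = "EPSG:3035"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def is_geographic(self) -> bool:
        return self.crs_id.upper() in ("EPSG:4326", "EPSG:4258")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres, shape (n_rows, n_cols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing a point; may fall outside the raster."""
        x0, y0 = self.origin
        col = int(math.floor((x - x0) / self.cell_size))
        row = int(math.floor((y0 - y) / self.cell_size))
        return row, col

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def conformal_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size, rel_tol=1e-9)
            and math.isclose(self.origin[0], other.origin[0], rel_tol=0, abs_tol=1e-6 * self.cell_size)
            and math.isclose(self.origin[1], other.origin[1], rel_tol=0, abs_tol=1e-6 * self.cell_size)
            and self.crs_id.upper() == other.crs_id.upper()
        )


def _require_conformal(a: RasterGrid, b: RasterGrid) -> None:
    if not a.conformal_with(b):
        raise GridConformanceError(f"grids are not conformal: {a} vs {b}")


@dataclass
class Layer:
    """A named single-band raster. Nodata cells are stored as NaN in memory."""

    grid: RasterGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise GridConformanceError(
                f"layer {self.name!r}: values shape {self.values.shape} != grid {self.grid.shape}"
            )

    @property
    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def copy(self, name: str | None = None) -> "Layer":
        return Layer(self.grid, self.values.copy(), self.name if name is None else name)


@dataclass
class Mask:
    """Boolean raster, conformal with its grid (e.g. the onshore mask)."""

    grid: RasterGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype != np.bool_:
            if not np.isin(np.unique(self.values), [0, 1]).all():
                raise ValueError("mask values must be boolean")
            self.values = self.values.astype(bool)
        if self.values.shape != self.grid.shape:
            raise GridConformanceError("mask shape does not match its grid")

    def __and__(self, other: "Mask") -> "Mask":
        _require_conformal(self.grid, other.grid)
        return Mask(self.grid, self.values & other.values)

    def __or__(self, other: "Mask") -> "Mask":
        _require_conformal(self.grid, other.grid)
        return Mask(self.grid, self.values | other.values)

    @property
    def n_true(self) -> int:
        return int(self.values.sum())


def cell_areas(grid: RasterGrid) -> Layer:
    """Per-cell area in km².

    Equal-area projected grids have constant cell area
    ``(cell_size / 1000)**2``.  Geographic grids use the exact
    spherical-quadrilateral area
    ``R² * dlon * (sin(lat_top) - sin(lat_bottom))`` per row.
    """
    if grid.is_geographic:
        x0, y0 = grid.origin
        lat_top = y0 - np.arange(grid.n_rows) * grid.cell_size
        lat_bot = lat_top - grid.cell_size
        dlon = math.radians(grid.cell_size)
        row_area = (
            EARTH_RADIUS_KM**2
            * dlon
            * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
        )
        values = np.repeat(row_area[:, None], grid.n_cols, axis=1)
    elif grid.crs_id.upper().startswith("EPSG:"):
        a = (grid.cell_size / 1000.0) ** 2
        values = np.full(grid.shape, a)
    else:
        raise ValueError(f"no area model for CRS {grid.crs_id!r}")
    return Layer(grid, values, name="cell_area_km2")


def mask_area_km2(mask: Mask, areas: Layer | None = None) -> float:
    """Total area of the true cells of a mask, in km²."""
    if areas is None:
        areas = cell_areas(mask.grid)
    _require_conformal(mask.grid, areas.grid)
    return float(areas.values[mask.values].sum())


# ---------------------------------------------------------------------------
# GeoTIFF I/O (single band; float32 for layers, uint8 for masks)
# ---------------------------------------------------------------------------

def _geo_extratags(grid: RasterGrid, nodata: float | None) -> list:
    cs = float(grid.cell_size)
    x0, y0 = map(float, grid.origin)
    epsg = 0
    code = grid.crs_id.upper()
    if code.startswith("EPSG:"):
        epsg = int(code.split(":")[1])
    if grid.is_geographic:
        keys = [1, 1, 0, 2, _KEY_MODEL_TYPE, 0, 1, 2, _KEY_GEOGRAPHIC_CS, 0, 1, epsg]
    else:
        keys = [1, 1, 0, 2, _KEY_MODEL_TYPE, 0, 1, 1, _KEY_PROJECTED_CS, 0, 1, epsg]
    tags = [
        (_TAG_PIXEL_SCALE, "d", 3, (cs, cs, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
        (_TAG_GEO_KEYS, "H", len(keys), tuple(keys)),
    ]
    if nodata is not None:
        s = repr(float(nodata))
        tags.append((_TAG_GDAL_NODATA, "s", len(s) + 1, s))
    return tags


def _parse_geotags(page) -> tuple[float, tuple[float, float], str, float | None]:
    tags = page.tags
    scale = tags[_TAG_PIXEL_SCALE].value
    tie = tags[_TAG_TIEPOINT].value
    cell_size = float(scale[0])
    origin = (float(tie[3]), float(tie[4]))
    crs_id = "EPSG:0"
    if _TAG_GEO_KEYS in tags:
        keys = list(tags[_TAG_GEO_KEYS].value)
        for i in range(4, len(keys), 4):
            kid, _, _, val = keys[i : i + 4]
            if kid in (_KEY_PROJECTED_CS, _KEY_GEOGRAPHIC_CS) and val:
                crs_id = f"EPSG:{val}"
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        try:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
        except ValueError:
            nodata = None
    return cell_size, origin, crs_id, nodata


def write_raster(path, layer: Layer) -> None:
    """Write a layer as a single-band float32 GeoTIFF; NaN → nodata sentinel."""
    grid = layer.grid
    data = layer.values.astype(np.float32)
    data = np.where(np.isfinite(data), data, np.float32(grid.nodata))
    tifffile.imwrite(
        path,
        data,
        extratags=_geo_extratags(grid, grid.nodata),
        metadata=None,
    )


def read_raster(path, expected_grid: RasterGrid | None = None, name: str = "") -> Layer:
    """Read a single-band GeoTIFF into a :class:`Layer`.

    Nodata cells (per the raster's GDAL_NODATA tag) are mapped to NaN.
    If ``expected_grid`` is given, a mismatching grid raises
    :class:`GridConformanceError`.
    """
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(np.float64)
        if data.ndim != 2:
            raise OSError(f"{path}: expected a single-band raster")
        cell_size, origin, crs_id, nodata = _parse_geotags(page)
    if nodata is None:
        nodata = -9999.0
    grid = RasterGrid(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        cell_size=cell_size,
        origin=origin,
        crs_id=crs_id,
        nodata=nodata,
    )
    if expected_grid is not None:
        if not grid.conformal_with(expected_grid):
            raise GridConformanceError(
                f"{path}: grid {grid} does not match expected {expected_grid}"
            )
        grid = expected_grid
    data = np.where(data == nodata, np.nan, data)
    return Layer(grid, data, name=name or str(path))


def write_mask(path, mask: Mask) -> None:
    """Write a boolean mask as a uint8 GeoTIFF (1 = true)."""
    tifffile.imwrite(
        path,
        mask.values.astype(np.uint8),
        extratags=_geo_extratags(mask.grid, None),
        metadata=None,
    )


def read_mask(path, expected_grid: RasterGrid | None = None) -> Mask:
    layer = read_raster(path, expected_grid=expected_grid)
    vals = np.nan_to_num(layer.values, nan=0.0)
    return Mask(layer.grid, vals > 0.5)
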