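"""Core raster/vector data model, GeoTIFF and GeoJSON I/O, resampling, water masking.

The in-memory raster container is :class:`Grid`: a single-band 2-D array of
floats in a projected (planar, metric) coordinate system, north-up, with an
explicit boolean nodata mask.  Every analysis stage in this package consumes
and produces Grids; all stages require their inputs to be pre-aligned to a
common grid (same transform, same shape) and raise otherwise — reprojection
and warping between coordinate systems are deliberately out of scope.

Rasters are read and written as plain single-band GeoTIFFs.  The georeferencing
is carried by the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, a
minimal GeoKeyDirectory holding the EPSG code) plus the GDAL_NODATA ASCII tag;
values are stored as float64 with NaN at nodata cells, so finite values
round-trip losslessly.

Zone and water polygons are read from GeoJSON (one feature per zone, identified
by a ``zone_id`` property) into shapely geometries.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
import tifffile
from scipy import ndimage
from shapely.geometry import MultiPolygon, Polygon, box, mapping
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry
from shapely.validation import make_valid

log = logging.getLogger(__name__)

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey ids
_KEY_GT_MODEL_TYPE = 1024
_KEY_GEOGRAPHIC_TYPE = 2048
_KEY_PROJECTED_CS_TYPE = 3072


@dataclass(frozen=True)
class GridTransform:
    """Affine mapping from array indices to projected coordinates.

    ``x0, y0`` is the outer corner of the top-left cell (north-west corner of
    the raster); ``dx`` is the cell width (east, > 0) and ``dy`` the cell
    height as stored (southward, < 0 for the north-up convention used
    throughout).
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or abs(self.dy) <= 0:
            raise ValueError("cell width and |cell height| must be positive")

    @property
    def cell_area(self) -> float:
        return self.dx * abs(self.dy)

    def cell_center(self, row, col):
        """Projected (x, y) of cell centers for (possibly array) indices."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.dx
        y = self.y0 + (np.asarray(row) + 0.5) * self.dy
        return x, y

    def extent(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full raster."""
        nrows, ncols = shape
        ys = sorted((self.y0, self.y0 + nrows * self.dy))
        return (self.x0, ys[0], self.x0 + ncols * self.dx, ys[1])


@dataclass
class Grid:
    """Single-band georeferenced raster with an explicit nodata mask."""

    values: np.ndarray
    transform: GridTransform
    crs_tag: str = "EPSG:32611"
    nodata_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("Grid values must be a 2-D array")
        if self.nodata_mask is None:
            self.nodata_mask = ~np.isfinite(self.values)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("values and nodata_mask must have identical shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_size(self) -> tuple[float, float]:
        return (self.transform.dx, abs(self.transform.dy))

    def data(self) -> np.ndarray:
        """Values with NaN substituted at nodata cells."""
        out = self.values.astype(float, copy=True)
        out[self.nodata_mask] = np.nan
        return out

    def with_values(self, values: np.ndarray, extra_mask: np.ndarray | None = None) -> "Grid":
        """New grid sharing this grid's georeferencing."""
        values = np.asarray(values, dtype=float)
        mask = ~np.isfinite(values)
        if values.shape == self.shape:
            mask |= self.nodata_mask
        if extra_mask is not None:
            mask |= extra_mask
        return Grid(values, self.transform, self.crs_tag, mask, dict(self.meta))

    def cell_centers(self):
        """Arrays (X, Y) of all cell-center coordinates."""
        rows, cols = np.indices(self.shape)
        return self.transform.cell_center(rows, cols)

    def assert_aligned(self, other: "Grid") -> None:
        if self.shape != other.shape:
            raise ValueError(f"grid shape mismatch: {self.shape} vs {other.shape}")
        t, u = self.transform, other.transform
        if not (
            math.isclose(t.x0, u.x0, abs_tol=1e-6)
            and math.isclose(t.y0, u.y0, abs_tol=1e-6)
            and math.isclose(t.dx, u.dx, rel_tol=1e-12)
            and math.isclose(t.dy, u.dy, rel_tol=1e-12)
        ):
            raise ValueError("grids are not aligned to a common transform")
        if self.crs_tag != other.crs_tag:
            raise ValueError(f"CRS mismatch: {self.crs_tag} vs {other.crs_tag}")


@dataclass
class ZoneSet:
    """Named appellation polygons plus an optional water exclusion mask."""

    zones: list[tuple[str, BaseGeometry]]
    water: BaseGeometry | None = None
    crs_tag: str | None = None

    def __post_init__(self) -> None:
        ids = [zid for zid, _ in self.zones]
        if len(ids) != len(set(ids)):
            dupes = sorted({z for z in ids if ids.count(z) > 1})
            raise ValueError(f"duplicate zone_id values: {dupes}")

    @property
    def zone_ids(self) -> list[str]:
        return [zid for zid, _ in self.zones]

    def geometry(self, zone_id: str) -> BaseGeometry:
        for zid, geom in self.zones:
            if zid == zone_id:
                return geom
        raise KeyError(f"unknown zone {zone_id!r}")

    def with_water(self, water: BaseGeometry | None) -> "ZoneSet":
        return ZoneSet(list(self.zones), water, self.crs_tag)


# ---------------------------------------------------------------------------
# raster I/O


def _epsg_from_tag(crs_tag: str) -> int | None:
    if crs_tag and crs_tag.upper().startswith("EPSG:"):
        try:
            return int(crs_tag.split(":", 1)[1])
        except ValueError:
            return None
    return None


def write_raster(grid: Grid, path: str | os.PathLike) -> None:
    """Write ``grid`` as a single-band float64 GeoTIFF.

    Nodata cells are stored as NaN and advertised via the GDAL_NODATA tag, so
    the write/read round trip is lossless for finite values, the transform,
    and the mask.
    """
    t = grid.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (t.dx, abs(t.dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.x0, t.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    epsg = _epsg_from_tag(grid.crs_tag)
    if epsg is not None:
        # minimal key directory: model type = projected, projected CS = EPSG code
        keys = (1, 1, 0, 2, _KEY_GT_MODEL_TYPE, 0, 1, 1, _KEY_PROJECTED_CS_TYPE, 0, 1, epsg)
        extratags.append((_TAG_GEO_KEY_DIRECTORY, "H", len(keys), keys))
    tifffile.imwrite(path, grid.data(), extratags=extratags)


def read_raster(path: str | os.PathLike) -> Grid:
    """Read a single-band georeferenced GeoTIFF into a :class:`Grid`.

    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` with
    distinct messages for multi-band files and files without georeferencing.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        samples = page.tags.get("SamplesPerPixel")
        if (samples is not None and samples.value != 1) or len(tif.pages) > 1:
            raise ValueError(f"multi-band raster not supported: {path}")
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise ValueError(f"multi-band raster not supported: {path}")
        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"raster has no georeferencing (GeoTIFF tags missing): {path}")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        tie = tie_tag.value
        # tiepoint maps raster (i, j) -> model (x, y); we require the 0,0 corner
        x0 = float(tie[3]) - float(tie[0]) * sx
        y0 = float(tie[4]) + float(tie[1]) * sy
        transform = GridTransform(x0, y0, sx, -sy)
        crs_tag = ""
        geokeys = page.tags.get(_TAG_GEO_KEY_DIRECTORY)
        if geokeys is not None:
            vals = list(geokeys.value)
            for k in range(4, len(vals) - 3, 4):
                key_id, _, _, value = vals[k : k + 4]
                if key_id in (_KEY_PROJECTED_CS_TYPE, _KEY_GEOGRAPHIC_TYPE):
                    crs_tag = f"EPSG:{value}"
        mask = ~np.isfinite(values)
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        if nodata_tag is not None:
            txt = str(nodata_tag.value).strip().strip("\x00")
            if txt and txt.lower() != "nan":
                mask |= values == float(txt)
    return Grid(values, transform, crs_tag or "EPSG:0", mask)


# ---------------------------------------------------------------------------
# vector I/O


def _load_geojson_features(path: str | os.PathLike) -> list[dict]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"vector file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc.get("features", []) if doc.get("type") == "FeatureCollection" else [doc]
    if not feats:
        raise ValueError(f"no features in {path}")
    return feats


def read_vector(
    path: str | os.PathLike,
    id_field: str = "zone_id",
    repair: bool = True,
) -> ZoneSet:
    """Read zone polygons from a GeoJSON file.

    Each feature must carry ``id_field`` in its properties; ids must be unique.
    Invalid (self-intersecting) polygons are repaired with ``make_valid`` when
    ``repair`` is true and rejected otherwise.
    """
    feats = _load_geojson_features(path)
    zones: list[tuple[str, BaseGeometry]] = []
    for feat in feats:
        props = feat.get("properties") or {}
        if id_field not in props:
            raise ValueError(f"feature missing id attribute {id_field!r} in {path}")
        geom = _geojson_shape(feat["geometry"])
        if not geom.is_valid:
            if repair:
                geom = make_valid(geom)
            else:
                raise ValueError(f"invalid geometry for zone {props[id_field]!r}")
        zones.append((str(props[id_field]), geom))
    return ZoneSet(zones)


def read_water(path: str | os.PathLike, repair: bool = True) -> BaseGeometry:
    """Read water-feature polygons from GeoJSON as one (multi)polygon union."""
    feats = _load_geojson_features(path)
    geoms = []
    for feat in feats:
        geom = _geojson_shape(feat["geometry"])
        if not geom.is_valid and repair:
            geom = make_valid(geom)
        geoms.append(geom)
    return shapely.union_all(geoms)


def write_vector(zones: ZoneSet, path: str | os.PathLike, id_field: str = "zone_id") -> None:
    """Write zone polygons as a GeoJSON FeatureCollection."""
    feats = [
        {"type": "Feature", "properties": {id_field: zid}, "geometry": mapping(geom)}
        for zid, geom in zones.zones
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


# ---------------------------------------------------------------------------
# resampling and masking


def resample(grid: Grid, target_cell: float, kind: str = "continuous") -> Grid:
    """Resample to a new square cell size over the same extent.

    Continuous data are interpolated bilinearly, categorical data by nearest
    neighbor.  Nodata is never interpolated across: any output cell whose
    bilinear stencil touches a nodata cell becomes nodata.
    """
    if target_cell <= 0:
        raise ValueError("target cell size must be positive")
    if kind not in ("continuous", "categorical"):
        raise ValueError(f"unknown resampling kind {kind!r}")
    t = grid.transform
    nrows, ncols = grid.shape
    width, height = ncols * t.dx, nrows * abs(t.dy)
    out_cols = max(1, int(round(width / target_cell)))
    out_rows = max(1, int(round(height / target_cell)))
    new_t = GridTransform(t.x0, t.y0, width / out_cols, -(height / out_rows))

    # fractional source indices of the output cell centers
    oc = (np.arange(out_cols) + 0.5) * new_t.dx / t.dx - 0.5
    orow = (np.arange(out_rows) + 0.5) * abs(new_t.dy) / abs(t.dy) - 0.5
    jj, ii = np.meshgrid(oc, orow)
    coords = np.stack([ii.ravel(), jj.ravel()])

    order = 1 if kind == "continuous" else 0
    vals = grid.values.astype(float, copy=True)
    vals[grid.nodata_mask] = 0.0
    out_vals = ndimage.map_coordinates(vals, coords, order=order, mode="nearest")
    bad = ndimage.map_coordinates(
        grid.nodata_mask.astype(float), coords, order=order, mode="nearest"
    )
    out_vals = out_vals.reshape(out_rows, out_cols)
    out_mask = (bad > 1e-12).reshape(out_rows, out_cols)
    out_vals[out_mask] = np.nan
    return Grid(out_vals, new_t, grid.crs_tag, out_mask, dict(grid.meta))


def apply_water_mask(grid: Grid, zones: ZoneSet) -> Grid:
    """Set cells whose centers fall inside water polygons to nodata.

    Cell membership is by cell-center containment, the same convention the
    zonal statistics use.  Idempotent; a missing/empty water set is a no-op.
    """
    if zones.crs_tag is not None and zones.crs_tag != grid.crs_tag:
        raise ValueError(f"CRS mismatch: grid {grid.crs_tag}, zones {zones.crs_tag}")
    if zones.water is None or zones.water.is_empty:
        return Grid(grid.values.copy(), grid.transform, grid.crs_tag,
                    grid.nodata_mask.copy(), dict(grid.meta))
    X, Y = grid.cell_centers()
    inside = shapely.contains_xy(zones.water, X.ravel(), Y.ravel()).reshape(grid.shape)
    vals = grid.values.astype(float, copy=True)
    vals[inside] = np.nan
    return Grid(vals, grid.transform, grid.crs_tag, grid.nodata_mask | inside, dict(grid.meta))
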