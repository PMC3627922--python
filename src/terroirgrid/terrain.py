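"""Slope, aspect, and aspect-sector classification from a DEM.

Gradients use Horn's 3x3 weighted finite differences, the default of the
mainstream GIS packages, so results are comparable with standard slope/aspect
layers.  Slope is expressed in percent rise (100 * rise/run); aspect is the
downslope azimuth in compass degrees (clockwise from north), with exactly-flat
cells marked by a sentinel and classed separately.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids_io import Grid

#: Aspect value marking cells with zero gradient.
FLAT = -1.0

#: Integer codes for the nine aspect categories (sidecar legend order).
ASPECT_CODES = {
    "Flat": 0, "N": 1, "NE": 2, "E": 3, "SE": 4, "S": 5, "SW": 6, "W": 7, "NW": 8,
}
ASPECT_NAMES = {v: k for k, v in ASPECT_CODES.items()}
_SECTOR_NAMES = ["N", "NE", "E", "SE", "S", "SW", "W", "NW"]

_HORN_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
_HORN_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)  # southward


def _horn_gradients(dem: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(dz/dx east, dz/dy north, output nodata mask) via Horn's stencil.

    Edges are handled by edge replication; nodata anywhere in a cell's 3x3
    neighborhood makes that output cell nodata.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3 for slope/aspect")
    z = dem.values.astype(float, copy=True)
    z[dem.nodata_mask] = 0.0  # placeholder; these outputs get masked below
    dx, dy = dem.cell_size
    gx = ndimage.correlate(z, _HORN_X, mode="nearest") / (8.0 * dx)
    gs = ndimage.correlate(z, _HORN_Y, mode="nearest") / (8.0 * dy)
    gn = -gs  # rows run southward; flip to a northward derivative
    out_mask = ndimage.binary_dilation(dem.nodata_mask, structure=np.ones((3, 3), bool))
    return gx, gn, out_mask


def compute_slope(dem: Grid) -> Grid:
    """Slope in percent rise: 100 * sqrt(gx^2 + gn^2)."""
    gx, gn, mask = _horn_gradients(dem)
    slope = 100.0 * np.hypot(gx, gn)
    slope[mask] = np.nan
    return Grid(slope, dem.transform, dem.crs_tag, mask, {"layer": "slope_pct"})


def compute_aspect(dem: Grid) -> Grid:
    """Downslope azimuth, degrees clockwise from north in [0, 360).

    The downslope direction is the negative gradient; its compass bearing is
    ``atan2(-gx, -gn)``.  Cells with exactly zero gradient get :data:`FLAT`.
    """
    gx, gn, mask = _horn_gradients(dem)
    aspect = np.degrees(np.arctan2(-gx, -gn)) % 360.0
    flat = (gx == 0.0) & (gn == 0.0)
    aspect[flat] = FLAT
    aspect[mask] = np.nan
    return Grid(aspect, dem.transform, dem.crs_tag, mask, {"layer": "aspect_deg"})


def classify_aspect(aspect: Grid) -> Grid:
    """Classify aspect into N, NE, ..., NW 45-degree sectors plus Flat.

    Sectors are centered on the cardinal/intercardinal azimuths and are
    left-closed/right-open, so N covers [337.5, 360) + [0, 22.5) and the
    boundary azimuth 337.5 itself falls in N.
    """
    az = aspect.values
    codes = np.full(aspect.shape, np.nan)
    valid = ~aspect.nodata_mask
    flat = valid & (az == FLAT)
    sloped = valid & ~flat
    sector = (np.floor((az + 22.5) / 45.0).astype(int)) % 8
    codes[sloped] = sector[sloped] + 1  # 1..8 = N..NW
    codes[flat] = ASPECT_CODES["Flat"]
    return Grid(codes, aspect.transform, aspect.crs_tag, aspect.nodata_mask.copy(),
                {"layer": "aspect_class", "legend": dict(ASPECT_CODES)})


def aspect_legend_text() -> str:
    """Sidecar legend for the integer-coded aspect-class raster."""
    lines = ["code\tcategory"]
    lines += [f"{code}\t{ASPECT_NAMES[code]}" for code in sorted(ASPECT_NAMES)]
    return "\n".join(lines) + "\n"
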