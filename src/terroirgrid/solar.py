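"""Clear-sky growing-season insolation from a DEM via horizon-angle viewsheds.

The model follows the hemispherical-viewshed family of topographic radiation
models: for every cell a horizon (maximum obstruction elevation angle) is
traced in a set of azimuth directions; direct radiation is accumulated over a
lattice of sun positions (day and hour steps across the season), attenuated by
a broadband transmissivity raised to the relative optical air mass, and
projected onto the sloped facet; diffuse radiation comes from a uniform sky
partitioned into zenith x azimuth sectors, each weighted by its unobstructed
solid angle and incidence on the facet.  The diffuse share is tied to the
configured diffuse proportion of global radiation on an unobstructed
horizontal surface.  Accumulated output is in watt-hours per square meter and
is intended as a comparative index of topographic exposure, not as a
measured-radiation climatology.

Large DEMs are processed in latitude bands (each band close to constant mean
latitude) with overlapping strips that are blended back with a linear ramp,
mirroring how single-latitude radiation tools are applied to tall rasters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids_io import Grid, GridTransform
from .terrain import FLAT

#: Rough meters per degree of latitude, used only to size latitude bands.
METERS_PER_DEGREE = 111_320.0


@dataclass
class SolarParams:
    """Configuration of the seasonal insolation model.

    Defaults are a growing-season (ordinal days 91-304, i.e. April-October)
    accumulation on a 14-day / 2-hour lattice, a 32-direction viewshed, an
    8 x 8 sky map with a 40,000-cell hemisphere discretization, a uniform
    diffuse model with diffuse proportion 0.3 and broadband transmissivity
    0.5 (generally clear skies).
    """

    latitude: float
    sky_cells: int = 40_000
    day_start: int = 91
    day_end: int = 304
    day_step: int = 14
    hour_step: float = 2.0
    n_azimuth_viewshed: int = 32
    n_zenith_div: int = 8
    n_azimuth_div: int = 8
    diffuse_model: str = "uniform"
    diffuse_proportion: float = 0.3
    transmissivity: float = 0.5
    solar_constant: float = 1367.0

    def __post_init__(self) -> None:
        if not (0.0 < self.diffuse_proportion < 1.0):
            raise ValueError("diffuse_proportion must be in (0, 1)")
        if not (0.0 <= self.transmissivity <= 1.0):
            raise ValueError("transmissivity must be in [0, 1]")
        if not (1 <= self.day_start <= self.day_end <= 366):
            raise ValueError("require 1 <= day_start <= day_end <= 366")
        if self.diffuse_model != "uniform":
            raise ValueError("only the uniform diffuse model is implemented")

    @property
    def viewshed_azimuths(self) -> np.ndarray:
        """Compass azimuths (degrees) of the viewshed directions."""
        return np.arange(self.n_azimuth_viewshed) * (360.0 / self.n_azimuth_viewshed)


@dataclass
class HorizonSet:
    """Per-cell horizon elevation angles (degrees) for each viewshed azimuth.

    ``angles`` has shape (nrows, ncols, n_azimuths); azimuth k corresponds to
    compass direction ``azimuths[k]``.
    """

    angles: np.ndarray
    azimuths: np.ndarray

    def __post_init__(self) -> None:
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 90.0):
            raise ValueError("horizon angles must lie in [0, 90] degrees")

    def interpolate(self, azimuth_deg: float) -> np.ndarray:
        """Horizon angle at an arbitrary azimuth, circular linear interpolation."""
        n = len(self.azimuths)
        step = 360.0 / n
        pos = (azimuth_deg % 360.0) / step
        i = int(np.floor(pos)) % n
        w = pos - np.floor(pos)
        return (1.0 - w) * self.angles[..., i] + w * self.angles[..., (i + 1) % n]


def declination(day: float) -> float:
    """Solar declination (degrees) from the Cooper approximation."""
    return 23.45 * math.sin(2.0 * math.pi * (284.0 + day) / 365.0)


def sun_positions(params: SolarParams) -> np.ndarray:
    """Lattice of above-horizon sun positions for the configured season.

    Returns a record array with fields ``day`` (ordinal), ``hour`` (local
    solar time), ``zenith`` and ``azimuth`` (degrees); positions below the
    astronomical horizon are excluded.  Each row represents a block of
    ``day_step`` days by ``hour_step`` hours.
    """
    lat = math.radians(params.latitude)
    rows = []
    for day in range(params.day_start, params.day_end + 1, params.day_step):
        dec = math.radians(declination(day))
        hour = 0.0
        while hour < 24.0:
            ha = math.radians(15.0 * (hour - 12.0))
            cos_z = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(ha)
            if cos_z > 0.0:
                east = -math.cos(dec) * math.sin(ha)
                north = math.cos(lat) * math.sin(dec) - math.sin(lat) * math.cos(dec) * math.cos(ha)
                az = math.degrees(math.atan2(east, north)) % 360.0
                rows.append((day, hour, math.degrees(math.acos(cos_z)), az))
            hour += params.hour_step
    return np.array(rows, dtype=[("day", int), ("hour", float),
                                 ("zenith", float), ("azimuth", float)])


def compute_horizon_angles(dem: Grid, params: SolarParams, max_radius: float) -> HorizonSet:
    """Maximum obstruction elevation angle along each viewshed azimuth.

    Rays are sampled at one-cell steps out to ``max_radius`` with bilinear
    interpolation of the DEM; samples falling outside the DEM are ignored, so
    an unobstructed direction yields angle 0.
    """
    dx, dy = dem.cell_size
    step = min(dx, dy)
    if max_radius < step:
        raise ValueError("max_radius must be at least one cell")
    z = dem.data()
    nrows, ncols = dem.shape
    rr, cc = np.indices((nrows, ncols)).astype(float)
    distances = np.arange(step, max_radius + 0.5 * step, step)
    azimuths = params.viewshed_azimuths
    angles = np.zeros((nrows, ncols, len(azimuths)))
    for k, az in enumerate(azimuths):
        east = math.sin(math.radians(az))
        north = math.cos(math.radians(az))
        best = np.full((nrows, ncols), -np.inf)
        for dist in distances:
            srow = rr - north * dist / dy
            scol = cc + east * dist / dx
            zs = ndimage.map_coordinates(z, [srow, scol], order=1,
                                         mode="constant", cval=np.nan)
            ang = np.degrees(np.arctan((zs - z) / dist))
            best = np.fmax(best, ang)
        best[~np.isfinite(best)] = 0.0
        angles[..., k] = np.clip(best, 0.0, 90.0)
    angles[dem.nodata_mask, :] = 0.0
    return HorizonSet(angles, azimuths)


def _facet_geometry(slope: Grid, aspect: Grid):
    """Slope angle (rad) and aspect (rad) with flat cells as horizontal."""
    beta = np.arctan(np.nan_to_num(slope.values, nan=0.0) / 100.0)
    az = aspect.values.copy()
    flat = az == FLAT
    az[flat] = 0.0
    beta[flat] = 0.0
    return beta, np.radians(az)


def compute_insolation(
    dem: Grid,
    slope: Grid,
    aspect: Grid,
    horizons: HorizonSet,
    params: SolarParams,
) -> Grid:
    """Seasonal global (direct + diffuse) insolation in Wh/m^2.

    Direct: for every sun-lattice position, beam irradiance is
    ``S0 * tau^m`` with relative air mass ``m = exp(-0.000118*elev)/cos(z)``,
    received as ``cos(incidence)`` on the facet when the sun stands above the
    local horizon; each position counts for ``day_step * hour_step`` hours.

    Diffuse: a uniform sky is split into ``n_zenith_div x n_azimuth_div``
    sectors; each contributes its unobstructed solid angle (gap fraction
    resolved on the hemisphere discretization implied by ``sky_cells``) times
    incidence on the facet, normalized so that an unobstructed horizontal cell
    receives exactly ``diffuse_proportion`` of global radiation.
    """
    dem.assert_aligned(slope)
    dem.assert_aligned(aspect)
    if horizons.angles.shape[:2] != dem.shape:
        raise ValueError("horizon set does not match DEM shape")
    positions = sun_positions(params)
    elev = np.nan_to_num(dem.values, nan=0.0)
    amf_elev = np.exp(-0.000118 * elev)
    beta, aspect_rad = _facet_geometry(slope, aspect)
    cos_b, sin_b = np.cos(beta), np.sin(beta)
    dt_hours = params.hour_step * params.day_step

    direct = np.zeros(dem.shape)
    direct_flat = np.zeros(dem.shape)  # unobstructed horizontal reference
    for pos in positions:
        z_rad = math.radians(pos["zenith"])
        cos_z, sin_z = math.cos(z_rad), math.sin(z_rad)
        m = amf_elev / max(cos_z, 1e-6)
        beam = params.solar_constant * params.transmissivity ** m
        visible = (90.0 - pos["zenith"]) > horizons.interpolate(pos["azimuth"])
        cos_i = cos_z * cos_b + sin_z * sin_b * np.cos(
            math.radians(pos["azimuth"]) - aspect_rad
        )
        direct += beam * np.clip(cos_i, 0.0, None) * dt_hours * visible
        direct_flat += beam * cos_z * dt_hours

    diffuse = _uniform_sky_diffuse(horizons, params, cos_b, sin_b, aspect_rad, direct_flat)
    total = direct + diffuse
    total[dem.nodata_mask] = np.nan
    return Grid(total, dem.transform, dem.crs_tag, dem.nodata_mask.copy(),
                {"layer": "insolation_wh_m2"})


def _uniform_sky_diffuse(horizons, params, cos_b, sin_b, aspect_rad, direct_flat):
    """Uniform-sky diffuse term, sector-decomposed and horizon-gated.

    The reference magnitude is ``dp/(1-dp) * direct_flat`` (so diffuse is
    ``dp`` of global on an unobstructed horizontal surface); the per-cell
    shape factor is the ratio of the sector sum (gap-weighted incidence on
    the facet) to the full-sky horizontal sector sum.
    """
    dp = params.diffuse_proportion
    ref = dp / (1.0 - dp) * direct_flat
    n_zen, n_az = params.n_zenith_div, params.n_azimuth_div
    # azimuth sub-sampling density implied by the hemisphere raster size
    n_fine = max(n_az, int(round(math.sqrt(params.sky_cells))))
    n_sub = max(1, n_fine // n_az)
    zen_edges = np.linspace(0.0, 90.0, n_zen + 1)
    zen_centers = 0.5 * (zen_edges[:-1] + zen_edges[1:])

    numerator = np.zeros_like(ref)
    denom = 0.0
    for ia in range(n_az):
        a0 = ia * 360.0 / n_az
        sector_az = math.radians(a0 + 180.0 / n_az)  # sector-center azimuth
        d_az = 2.0 * math.pi / n_fine  # solid-angle width per sub-azimuth
        for isub in range(n_sub):
            az = a0 + (isub + 0.5) * (360.0 / n_az) / n_sub
            h = horizons.interpolate(az)  # (nrows, ncols)
            zen_vis_max = 90.0 - h  # visible down to this zenith angle
            for iz in range(n_zen):
                z1, z2 = zen_edges[iz], zen_edges[iz + 1]
                zc = math.radians(zen_centers[iz])
                # visible part of [z1, z2]: solid angle ∝ cos z1 − cos z_top
                z_top = np.clip(zen_vis_max, z1, z2)
                omega = d_az * (math.cos(math.radians(z1)) - np.cos(np.radians(z_top)))
                cos_i = (math.cos(zc) * cos_b
                         + math.sin(zc) * sin_b * np.cos(sector_az - aspect_rad))
                numerator += omega * np.clip(cos_i, 0.0, None)
                omega_full = d_az * (math.cos(math.radians(z1)) - math.cos(math.radians(z2)))
                denom += omega_full * math.cos(zc)
    return ref * numerator / denom


# ---------------------------------------------------------------------------
# latitude-band tiling and blended mosaicking


def tile_by_latitude(dem: Grid, max_extent_deg: float, overlap: float) -> list[Grid]:
    """Split a DEM into north-south bands of bounded latitude span.

    Each band spans at most ``max_extent_deg`` of latitude (converted with a
    constant meters-per-degree factor); adjacent bands share an ``overlap``
    strip so that horizon effects near internal edges can be blended away.
    Band grids carry ``meta['tile_rows']`` with their global row range.
    """
    if overlap < 0:
        raise ValueError("overlap must be non-negative")
    nrows, ncols = dem.shape
    cell_h = abs(dem.transform.dy)
    span_deg = nrows * cell_h / METERS_PER_DEGREE
    n_tiles = max(1, int(math.ceil(span_deg / max_extent_deg)))
    if n_tiles == 1:
        out = Grid(dem.values.copy(), dem.transform, dem.crs_tag,
                   dem.nodata_mask.copy(), dict(dem.meta))
        out.meta["tile_rows"] = (0, nrows)
        return [out]
    ov_rows = int(round(overlap / cell_h))
    bounds = [int(round(i * nrows / n_tiles)) for i in range(n_tiles + 1)]
    core = min(bounds[i + 1] - bounds[i] for i in range(n_tiles))
    if ov_rows >= core:
        raise ValueError("overlap strip is larger than a tile")
    tiles = []
    for i in range(n_tiles):
        start = bounds[i] - (ov_rows if i > 0 else 0)
        end = bounds[i + 1]
        t = dem.transform
        sub_t = GridTransform(t.x0, t.y0 + start * t.dy, t.dx, t.dy)
        sub = Grid(dem.values[start:end].copy(), sub_t, dem.crs_tag,
                   dem.nodata_mask[start:end].copy(), dict(dem.meta))
        sub.meta["tile_rows"] = (start, end)
        tiles.append(sub)
    return tiles


def mean_latitude(grid: Grid, reference_latitude: float, reference_y: float) -> float:
    """Mean latitude of a band, offset from a reference northing.

    With projected northings, latitude is approximated as linear in y with the
    constant meters-per-degree factor — adequate for sizing/centering bands.
    """
    nrows = grid.shape[0]
    y_mid = grid.transform.y0 + 0.5 * nrows * grid.transform.dy
    return reference_latitude + (y_mid - reference_y) / METERS_PER_DEGREE


def blend_mosaic(tiles: list[Grid]) -> Grid:
    """Re-assemble latitude-band outputs with linear-ramp blending.

    Outside overlap strips the mosaic equals the unique covering tile; inside
    a strip it is the convex combination of the two tiles with weights ramping
    linearly across the strip, so the mosaic always lies between the two tile
    values there.
    """
    if not tiles:
        raise ValueError("no tiles to mosaic")
    spans = sorted((t.meta["tile_rows"], i) for i, t in enumerate(tiles))
    order = [i for _, i in spans]
    spans = [s for s, _ in spans]
    nrows = spans[-1][1]
    ncols = tiles[0].shape[1]
    for k in range(len(spans) - 1):
        if spans[k + 1][0] > spans[k][1]:
            raise ValueError("gap between tiles")
    first = tiles[order[0]]
    t = first.transform
    full_t = GridTransform(t.x0, t.y0 - spans[0][0] * t.dy, t.dx, t.dy)
    acc = np.zeros((nrows, ncols))
    wacc = np.zeros((nrows, ncols))
    for k, idx in enumerate(order):
        tile = tiles[idx]
        s, e = spans[k]
        w = np.ones(e - s)
        if k > 0:  # ramp up across the strip shared with the tile above
            ov = spans[k - 1][1] - s
            if ov > 0:
                w[:ov] = (np.arange(ov) + 0.5) / ov
        if k < len(order) - 1:  # ramp down into the strip shared below
            ov = e - spans[k + 1][0]
            if ov > 0:
                w[-ov:] = np.minimum(w[-ov:], ((np.arange(ov) + 0.5) / ov)[::-1])
        vals = np.nan_to_num(tile.data(), nan=0.0)
        valid = (~tile.nodata_mask).astype(float)
        acc[s:e] += w[:, None] * vals * valid
        wacc[s:e] += w[:, None] * valid
    with np.errstate(invalid="ignore"):
        out = acc / wacc
    mask = wacc == 0.0
    out[mask] = np.nan
    return Grid(out, full_t, first.crs_tag, mask, {"layer": first.meta.get("layer", "")})


def insolation_pipeline(
    dem: Grid,
    params: SolarParams,
    max_radius: float,
    slope: Grid | None = None,
    aspect: Grid | None = None,
    max_extent_deg: float | None = None,
    overlap: float | None = None,
) -> Grid:
    """Convenience wrapper: terrain, horizons, insolation, optional tiling.

    When ``max_extent_deg`` is given the DEM is processed in latitude bands
    (each with its own mean latitude) and blended back together.
    """
    from . import terrain  # local import to avoid cycle at module load

    if slope is None:
        slope = terrain.compute_slope(dem)
    if aspect is None:
        aspect = terrain.compute_aspect(dem)
    if max_extent_deg is None:
        horizons = compute_horizon_angles(dem, params, max_radius)
        return compute_insolation(dem, slope, aspect, horizons, params)
    if overlap is None:
        overlap = max_radius
    tiles = tile_by_latitude(dem, max_extent_deg, overlap)
    y_ref = dem.transform.y0 + 0.5 * dem.shape[0] * dem.transform.dy
    outputs = []
    for tile in tiles:
        s, e = tile.meta["tile_rows"]
        tp = SolarParams(**{**params.__dict__,
                            "latitude": mean_latitude(tile, params.latitude, y_ref)})
        t_slope = terrain.compute_slope(tile)
        t_aspect = terrain.compute_aspect(tile)
        hz = compute_horizon_angles(tile, tp, max_radius)
        out = compute_insolation(tile, t_slope, t_aspect, hz, tp)
        out.meta["tile_rows"] = (s, e)
        outputs.append(out)
    return blend_mosaic(outputs)
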