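"""Synthetic fixture generator: DEMs, climate normals, soil surveys, zones.

Real inputs to this pipeline are large public archives (an elevation model,
gridded monthly climate normals, a soil survey).  The generators here emulate
the statistical structure those archives share — elevation-dependent
temperature (a linear lapse rate), elevation-dependent precipitation and
frost dates, polygonal map units with component/horizon tables, and named
zone polygons — so every stage is testable offline at small sizes.  Every
generator is a pure function of its configuration, whose ``seed`` fully
determines the output; analytic ground truth (plane gradients, lapse rates,
dominant components) is recorded in metadata for oracle tests.

The coupling of climate to elevation is deliberately minimal: linear trends
plus independent Gaussian noise.  No attempt is made to emulate the regression
machinery, spatial autocorrelation, coastal/orographic effects or categorical
complexity of the real archives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from shapely.geometry import MultiPoint, box
from shapely.ops import voronoi_diagram

from .climate_indices import SEASON_MONTHS, MonthlyNormals
from .grids_io import Grid, GridTransform, ZoneSet
from .soils import DRAINAGE_CLASSES, Component, Horizon, SoilSurvey

#: Sea-level monthly mean temperature (degC), April..October — an inland
#: temperate-steppe seasonal curve.
SEA_LEVEL_TAVG = {4: 10.5, 5: 14.5, 6: 18.5, 7: 22.0, 8: 21.5, 9: 17.0, 10: 10.5}

#: Base monthly precipitation (mm) at reference elevation, April..October —
#: a dry-summer inland regime.
BASE_MONTHLY_PPT = {4: 30.0, 5: 28.0, 6: 22.0, 7: 12.0, 8: 12.0, 9: 16.0, 10: 28.0}


@dataclass
class FixtureConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe a 60 x 80 cell, 30 m grid in a projected CRS at about
    46.5 degrees north with a -6.5 degC/km lapse rate, +50 mm/km
    precipitation-elevation gradient, frost dates tightening by 3 days per
    100 m of elevation, a 12 degC diurnal range, and modest measurement
    noise.  ``seed`` fully determines every generated output.
    """

    shape: tuple[int, int] = (60, 80)
    cell: float = 30.0
    origin: tuple[float, float] = (500_000.0, 5_150_000.0)
    crs_tag: str = "EPSG:32611"
    latitude: float = 46.5
    dem_kind: str = "composite"
    base_elevation: float = 200.0
    gradient: tuple[float, float] = (0.03, 0.04)  # dz/dx, dz/dy (north)
    amplitude: float = 120.0
    lapse_rate: float = -6.5  # degC per km of elevation
    ppt_gradient: float = 50.0  # mm per km of elevation, per season spread monthly
    frost_coupling: float = 3.0  # days per 100 m of elevation
    diurnal_range: float = 12.0  # degC, tmax - tmin
    noise_sd_t: float = 0.2  # degC
    noise_sd_ppt: float = 2.0  # mm per month
    noise_sd_frost: float = 1.5  # days
    n_mapunits: int = 6
    n_zones: int = 4
    with_water: bool = False
    seed: int = 0

    def transform(self) -> GridTransform:
        return GridTransform(self.origin[0], self.origin[1], self.cell, -self.cell)


def _local_xy(config: FixtureConfig):
    """Cell-center coordinates relative to the grid's south-west corner (m)."""
    nrows, ncols = config.shape
    x = (np.arange(ncols) + 0.5) * config.cell
    y = ((nrows - np.arange(nrows)) - 0.5) * config.cell  # northward
    return np.meshgrid(x, y)


def make_dem(config: FixtureConfig) -> Grid:
    """Analytic DEM: plane, Gaussian hill, incised valley, or composite.

    The analytic parameters are recorded in ``meta`` so terrain tests can
    check slope/aspect against closed forms.
    """
    X, Y = _local_xy(config)
    gx, gy = config.gradient
    nrows, ncols = config.shape
    width, height = ncols * config.cell, nrows * config.cell
    if config.dem_kind == "plane":
        z = config.base_elevation + gx * X + gy * Y
    elif config.dem_kind == "hill":
        sigma = 0.2 * min(width, height)
        z = config.base_elevation + config.amplitude * np.exp(
            -((X - width / 2) ** 2 + (Y - height / 2) ** 2) / (2 * sigma**2)
        )
    elif config.dem_kind == "valley":
        half = 0.15 * width
        z = config.base_elevation + config.amplitude * (
            1.0 - np.exp(-((X - width / 2) ** 2) / (2 * half**2))
        )
    elif config.dem_kind == "composite":
        sigma = 0.2 * min(width, height)
        z = (config.base_elevation + gx * X + gy * Y
             + config.amplitude * np.exp(
                 -((X - width / 2) ** 2 + (Y - height / 2) ** 2) / (2 * sigma**2)))
    else:
        raise ValueError(f"unknown dem_kind {config.dem_kind!r}")
    return Grid(z, config.transform(), config.crs_tag,
                np.zeros(config.shape, bool),
                {"layer": "elevation_m", "dem_kind": config.dem_kind,
                 "gradient": config.gradient, "amplitude": config.amplitude,
                 "base_elevation": config.base_elevation})


def make_monthly_normals(dem: Grid, config: FixtureConfig) -> MonthlyNormals:
    """Elevation-coupled monthly normals and frost-date surfaces.

    Per month: ``tavg = sea-level curve + lapse_rate * elev/1000 + noise``;
    tmax/tmin are tavg plus/minus half the fixed diurnal range (so
    tmax >= tmin by construction); ``ppt = base + ppt_gradient * elev/1000 / 7
    + noise`` clipped at zero.  Frost dates move with elevation by
    ``frost_coupling`` days per 100 m in both directions, with
    ``first_fall >= last_spring`` enforced.
    """
    rng = np.random.default_rng(config.seed + 1)
    elev = dem.data()
    km = elev / 1000.0
    half = config.diurnal_range / 2.0
    tmax, tmin, ppt = {}, {}, {}
    for m in SEASON_MONTHS:
        tavg = (SEA_LEVEL_TAVG[m] + config.lapse_rate * km
                + rng.normal(0.0, config.noise_sd_t, dem.shape) * (config.noise_sd_t > 0))
        tmax[m] = dem.with_values(tavg + half)
        tmin[m] = dem.with_values(tavg - half)
        p = (BASE_MONTHLY_PPT[m] + config.ppt_gradient * km / len(SEASON_MONTHS)
             + rng.normal(0.0, config.noise_sd_ppt, dem.shape) * (config.noise_sd_ppt > 0))
        ppt[m] = dem.with_values(np.clip(p, 0.0, None))
    shift = config.frost_coupling * elev / 100.0
    spring = 110.0 + shift + rng.normal(0.0, config.noise_sd_frost, dem.shape) * (
        config.noise_sd_frost > 0)
    fall = 285.0 - shift + rng.normal(0.0, config.noise_sd_frost, dem.shape) * (
        config.noise_sd_frost > 0)
    fall = np.maximum(fall, spring)
    return MonthlyNormals(
        tmax=tmax, tmin=tmin, ppt=ppt,
        last_spring_frost=dem.with_values(np.clip(spring, 1, 366)),
        first_fall_frost=dem.with_values(np.clip(fall, 1, 366)),
    )


def make_soil_survey(config: FixtureConfig) -> SoilSurvey:
    """Voronoi-cell map units with component and horizon tables.

    Each map unit gets 1-3 components with integer percents summing to 100,
    each component 2-4 horizons with AWC in 0.05-0.25 cm/cm, pH in 5.5-8.5
    and an optional restrictive depth.  The per-map-unit dominant component
    and its attribute values are recorded in ``meta['truth']`` for
    self-consistency oracles.
    """
    if config.n_mapunits < 1:
        raise ValueError("n_mapunits must be >= 1")
    rng = np.random.default_rng(config.seed + 2)
    nrows, ncols = config.shape
    x0, y0 = config.origin
    extent_box = box(x0, y0 - nrows * config.cell, x0 + ncols * config.cell, y0)
    if config.n_mapunits == 1:
        polys = [extent_box]
    else:
        xs = rng.uniform(x0, x0 + ncols * config.cell, config.n_mapunits)
        ys = rng.uniform(y0 - nrows * config.cell, y0, config.n_mapunits)
        cells = voronoi_diagram(MultiPoint(list(zip(xs, ys))), envelope=extent_box)
        polys = [g.intersection(extent_box) for g in cells.geoms]
        polys = [p for p in polys if not p.is_empty]
    components: list[Component] = []
    horizons: list[Horizon] = []
    mapunits = []
    truth: dict[str, dict] = {}
    drainage_p = np.array([0.05, 0.10, 0.60, 0.10, 0.10, 0.04, 0.01])
    for i, poly in enumerate(polys):
        mukey = f"mu{i + 1:03d}"
        mapunits.append((mukey, poly))
        n_comp = int(rng.integers(1, 4))
        raw = rng.uniform(0.5, 1.0, n_comp)
        pct = np.floor(100.0 * raw / raw.sum()).astype(int)
        pct[0] += 100 - pct.sum()
        comp_records = []
        for j in range(n_comp):
            cokey = f"{mukey}c{j + 1}"
            drainage = str(rng.choice(DRAINAGE_CLASSES, p=drainage_p))
            depth = float(np.round(rng.uniform(20.0, 200.0), 0)) if rng.random() < 0.6 else None
            components.append(Component(mukey, cokey, float(pct[j]), drainage, depth))
            n_hz = int(rng.integers(2, 5))
            bounds = np.sort(rng.uniform(10.0, 150.0, n_hz - 1))
            tops = np.concatenate([[0.0], bounds])
            bottoms = np.concatenate([bounds, [bounds[-1] + rng.uniform(20.0, 60.0)
                                               if n_hz > 1 else 100.0]])
            hz = [Horizon(cokey, float(t), float(b),
                          awc=float(np.round(rng.uniform(0.05, 0.25), 3)),
                          ph=float(np.round(rng.uniform(5.5, 8.5), 2)))
                  for t, b in zip(tops, bottoms)]
            horizons.extend(hz)
            comp_records.append((cokey, float(pct[j]), drainage, depth, hz))
        # ground truth: inline dominant-component logic (largest percent,
        # lexicographic tie-break), independent of the soils module
        dom = sorted(comp_records, key=lambda r: (-r[1], r[0]))[0]

        def _weighted(hz_list, attr):
            num = den = 0.0
            for h in hz_list:
                ov = min(h.bottom, 50.0) - max(h.top, 0.0)
                if ov > 0:
                    num += getattr(h, attr) * ov
                    den += ov
            return num / den if den else None

        truth[mukey] = {
            "cokey": dom[0],
            "drainage_class": dom[2],
            "depth": dom[3] if dom[3] is not None else 200.0,
            "awc": _weighted(dom[4], "awc"),
            "ph": _weighted(dom[4], "ph"),
        }
    survey = SoilSurvey(mapunits, components, horizons, config.crs_tag)
    survey.meta["truth"] = truth
    return survey


def make_zones(config: FixtureConfig) -> ZoneSet:
    """Non-overlapping rectangular zones spanning the extent west to east.

    Zone ``zone01`` is westernmost.  With ``with_water`` a rectangular water
    body is placed across the southern edge.  Polygon areas are recorded on
    the returned object's zones via the geometries themselves.
    """
    if config.n_zones < 1:
        raise ValueError("n_zones must be >= 1")
    nrows, ncols = config.shape
    x0, y0 = config.origin
    ymin = y0 - nrows * config.cell
    width = ncols * config.cell
    zones = []
    for i in range(config.n_zones):
        xa = x0 + i * width / config.n_zones
        xb = x0 + (i + 1) * width / config.n_zones
        zones.append((f"zone{i + 1:02d}", box(xa, ymin, xb, y0)))
    water = None
    if config.with_water:
        water = box(x0 + 0.25 * width, ymin, x0 + 0.55 * width,
                    ymin + 0.2 * nrows * config.cell)
    return ZoneSet(zones, water, config.crs_tag)


def make_fixture(config: FixtureConfig):
    """DEM, normals, survey and zones in one call (shared config/seed)."""
    dem = make_dem(config)
    return dem, make_monthly_normals(dem, config), make_soil_survey(config), make_zones(config)
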