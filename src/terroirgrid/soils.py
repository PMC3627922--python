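"""SSURGO-like soil survey model and thematic rasterization.

A soil survey here is the minimal slice of the SSURGO schema the thematic
maps need: map-unit polygons, a component table (area percent, drainage
class, depth to any restrictive layer) and a horizon table (depth interval,
available water capacity, pH).  Map units are reduced to a single value per
attribute by dominant-component aggregation (the component with the largest
area percent; a dominant-condition variant is available for categorical
attributes), profile attributes are depth-weighted over the 0-50 cm window,
and the result is rasterized at 10 m by cell-center containment.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import mapping
from shapely.geometry import shape as _geojson_shape
from shapely.geometry.base import BaseGeometry

from .grids_io import Grid, GridTransform

#: Ordered drainage classes, excessively drained .. very poorly drained.
DRAINAGE_CLASSES = ("ED", "SED", "WD", "MWD", "SPD", "PD", "VPD")
DRAINAGE_CODES = {name: i + 1 for i, name in enumerate(DRAINAGE_CLASSES)}
DRAINAGE_NAMES = {v: k for k, v in DRAINAGE_CODES.items()}

#: Depth assigned when no restrictive layer was found within the survey depth.
SURVEY_MAX_DEPTH = 200.0  # cm

#: Depth window (cm) for profile-weighted AWC and pH.
DEFAULT_WINDOW = (0.0, 50.0)

ATTRIBUTES = ("drainage_class", "depth", "awc", "ph")


@dataclass
class Horizon:
    cokey: str
    top: float  # cm
    bottom: float  # cm
    awc: float | None = None  # cm water / cm soil
    ph: float | None = None

    def __post_init__(self) -> None:
        if not self.top < self.bottom:
            raise ValueError(f"horizon top must be < bottom ({self.cokey})")


@dataclass
class Component:
    mukey: str
    cokey: str
    percent: float
    drainage_class: str
    depth_to_restrictive: float | None = None  # cm; None = none found

    def __post_init__(self) -> None:
        if self.drainage_class not in DRAINAGE_CLASSES:
            raise ValueError(f"unknown drainage class {self.drainage_class!r}")
        if not (0 <= self.percent <= 100):
            raise ValueError("component percent must be in [0, 100]")


@dataclass
class SoilSurvey:
    """Map-unit polygons plus component and horizon tables."""

    mapunits: list[tuple[str, BaseGeometry]]
    components: list[Component]
    horizons: list[Horizon]
    crs_tag: str = "EPSG:32611"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [mk for mk, _ in self.mapunits]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate mukey values")
        by_mu: dict[str, float] = {}
        for c in self.components:
            by_mu[c.mukey] = by_mu.get(c.mukey, 0.0) + c.percent
        for mk, total in by_mu.items():
            if total > 100.0 + 1e-9:
                raise ValueError(f"component percents for {mk} sum to {total} > 100")
        by_co: dict[str, list[Horizon]] = {}
        for h in self.horizons:
            by_co.setdefault(h.cokey, []).append(h)
        for cokey, hs in by_co.items():
            hs = sorted(hs, key=lambda h: h.top)
            for a, b in zip(hs, hs[1:]):
                if b.top < a.bottom - 1e-9:
                    raise ValueError(f"overlapping horizons for component {cokey}")

    @property
    def mukeys(self) -> list[str]:
        return [mk for mk, _ in self.mapunits]

    def components_of(self, mukey: str) -> list[Component]:
        if mukey not in self.mukeys:
            raise KeyError(f"unknown mukey {mukey!r}")
        return [c for c in self.components if c.mukey == mukey]

    def horizons_of(self, cokey: str) -> list[Horizon]:
        return sorted((h for h in self.horizons if h.cokey == cokey), key=lambda h: h.top)

    def component(self, cokey: str) -> Component:
        for c in self.components:
            if c.cokey == cokey:
                return c
        raise KeyError(f"unknown cokey {cokey!r}")


# ---------------------------------------------------------------------------
# aggregation


def select_dominant_component(survey: SoilSurvey, mukey: str) -> str:
    """Component with the largest area percent; ties go to the smallest cokey."""
    comps = survey.components_of(mukey)
    if not comps:
        raise ValueError(f"map unit {mukey!r} has no components")
    return min(comps, key=lambda c: (-c.percent, c.cokey)).cokey


def dominant_condition(survey: SoilSurvey, mukey: str, attribute: str = "drainage_class") -> str:
    """Dominant-condition aggregation for a categorical attribute.

    Percents are summed over components sharing a class; the class with the
    largest total wins, ties broken by class order (ED first).
    """
    if attribute != "drainage_class":
        raise ValueError("dominant condition applies to categorical attributes only")
    comps = survey.components_of(mukey)
    if not comps:
        raise ValueError(f"map unit {mukey!r} has no components")
    totals: dict[str, float] = {}
    for c in comps:
        totals[c.drainage_class] = totals.get(c.drainage_class, 0.0) + c.percent
    return min(totals, key=lambda k: (-totals[k], DRAINAGE_CODES[k]))


def depth_weighted_mean(
    horizons: list[Horizon],
    attribute: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float | None:
    """Thickness-weighted mean of ``awc`` or ``ph`` over a depth window.

    Horizons with a missing value are excluded and their thickness removed
    from the denominator; no coverage in the window returns None.
    """
    if attribute not in ("awc", "ph"):
        raise ValueError(f"unknown profile attribute {attribute!r}")
    lo, hi = window
    num = den = 0.0
    for h in horizons:
        value = getattr(h, attribute)
        if value is None:
            continue
        overlap = min(h.bottom, hi) - max(h.top, lo)
        if overlap > 0:
            num += value * overlap
            den += overlap
    return num / den if den > 0 else None


def depth_to_restrictive(
    survey: SoilSurvey, cokey: str, survey_max: float = SURVEY_MAX_DEPTH
) -> float:
    """Recorded restrictive-layer depth, or the censored survey maximum."""
    comp = survey.component(cokey)
    return comp.depth_to_restrictive if comp.depth_to_restrictive is not None else survey_max


def component_attribute(survey: SoilSurvey, cokey: str, attribute: str) -> float | None:
    """One numeric value of ``attribute`` for a component (codes for classes)."""
    if attribute == "drainage_class":
        return float(DRAINAGE_CODES[survey.component(cokey).drainage_class])
    if attribute == "depth":
        return depth_to_restrictive(survey, cokey)
    if attribute in ("awc", "ph"):
        return depth_weighted_mean(survey.horizons_of(cokey), attribute)
    raise ValueError(f"unknown attribute {attribute!r}")


def mapunit_attribute(
    survey: SoilSurvey, mukey: str, attribute: str, method: str = "dominant_component"
) -> float | None:
    """Aggregate one attribute for a map unit."""
    if method == "dominant_component":
        return component_attribute(survey, select_dominant_component(survey, mukey), attribute)
    if method == "dominant_condition":
        return float(DRAINAGE_CODES[dominant_condition(survey, mukey, attribute)])
    raise ValueError(f"unknown aggregation method {method!r}")


def rasterize_attribute(
    survey: SoilSurvey,
    attribute: str,
    cell: float = 10.0,
    extent: tuple[float, float, float, float] | None = None,
    method: str = "dominant_component",
) -> Grid:
    """Rasterize a map-unit-aggregated attribute at ``cell`` meters.

    Each cell takes the value of the map unit containing its center; cells
    outside every map unit are nodata.  10 m is fine enough to represent the
    map-unit boundaries at the survey scales this mirrors.
    """
    if attribute not in ATTRIBUTES:
        raise ValueError(f"unknown attribute {attribute!r}; expected one of {ATTRIBUTES}")
    if extent is None:
        xs, ys = [], []
        for _, geom in survey.mapunits:
            b = geom.bounds
            xs += [b[0], b[2]]
            ys += [b[1], b[3]]
        extent = (min(xs), min(ys), max(xs), max(ys))
    xmin, ymin, xmax, ymax = extent
    ncols = max(1, int(round((xmax - xmin) / cell)))
    nrows = max(1, int(round((ymax - ymin) / cell)))
    transform = GridTransform(xmin, ymax, cell, -cell)
    values = np.full((nrows, ncols), np.nan)
    rows, cols = np.indices((nrows, ncols))
    X, Y = transform.cell_center(rows, cols)
    xf, yf = X.ravel(), Y.ravel()
    assigned = np.zeros(xf.shape, dtype=bool)
    flat = values.ravel()
    for mukey, geom in survey.mapunits:
        inside = shapely.contains_xy(geom, xf, yf) & ~assigned
        if not inside.any():
            continue
        val = mapunit_attribute(survey, mukey, attribute, method)
        flat[inside] = np.nan if val is None else val
        assigned |= inside
    values = flat.reshape(nrows, ncols)
    return Grid(values, transform, survey.crs_tag, ~np.isfinite(values),
                {"layer": attribute, "aggregation": method})


def drainage_legend_text() -> str:
    """Sidecar legend for the integer-coded drainage-class raster."""
    lines = ["code\tclass"]
    lines += [f"{code}\t{DRAINAGE_NAMES[code]}" for code in sorted(DRAINAGE_NAMES)]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# survey I/O (GeoJSON map units + CSV component/horizon tables)


def load_soil_survey(
    mapunit_path: str | os.PathLike,
    component_path: str | os.PathLike,
    horizon_path: str | os.PathLike,
) -> SoilSurvey:
    """Read a survey from a map-unit GeoJSON and component/horizon CSVs."""
    with open(mapunit_path) as fh:
        doc = json.load(fh)
    mapunits = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "mukey" not in props:
            raise ValueError("map unit feature missing 'mukey' attribute")
        mapunits.append((str(props["mukey"]), _geojson_shape(feat["geometry"])))

    def _opt(v: str) -> float | None:
        return None if v in ("", "NA", "None") else float(v)

    components, horizons = [], []
    with open(component_path, newline="") as fh:
        for row in csv.DictReader(fh):
            components.append(Component(
                mukey=row["mukey"], cokey=row["cokey"], percent=float(row["percent"]),
                drainage_class=row["drainage_class"],
                depth_to_restrictive=_opt(row.get("depth_to_restrictive", "")),
            ))
    with open(horizon_path, newline="") as fh:
        for row in csv.DictReader(fh):
            horizons.append(Horizon(
                cokey=row["cokey"], top=float(row["top"]), bottom=float(row["bottom"]),
                awc=_opt(row.get("awc", "")), ph=_opt(row.get("ph", "")),
            ))
    return SoilSurvey(mapunits, components, horizons)


def write_soil_survey(
    survey: SoilSurvey,
    mapunit_path: str | os.PathLike,
    component_path: str | os.PathLike,
    horizon_path: str | os.PathLike,
) -> None:
    """Write a survey as map-unit GeoJSON plus component/horizon CSVs."""
    feats = [
        {"type": "Feature", "properties": {"mukey": mk}, "geometry": mapping(geom)}
        for mk, geom in survey.mapunits
    ]
    with open(mapunit_path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
    with open(component_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["mukey", "cokey", "percent", "drainage_class", "depth_to_restrictive"])
        for c in survey.components:
            w.writerow([c.mukey, c.cokey, c.percent, c.drainage_class,
                        "" if c.depth_to_restrictive is None else c.depth_to_restrictive])
    with open(horizon_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cokey", "top", "bottom", "awc", "ph"])
        for h in survey.horizons:
            w.writerow([h.cokey, h.top, h.bottom,
                        "" if h.awc is None else h.awc, "" if h.ph is None else h.ph])
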