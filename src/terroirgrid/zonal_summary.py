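"""Per-appellation zonal summaries and inter-zone contrasts.

This stage restates the study's summary machinery: per-zone means of the
continuous surfaces (the site-characteristics table), per-zone class
proportions for drainage class and aspect sector, unweighted cross-zone
column averages, and signed pairwise contrasts (including the GDD-BEDD gap,
a measure of how front-loaded a zone's heat accumulation is).

Zone membership is by cell-center containment, matching the raster masking
convention; water should already have been masked out of the input grids.
Summaries are assembled into a pandas DataFrame with one row per zone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .grids_io import Grid, ZoneSet
from .soils import DRAINAGE_CLASSES, DRAINAGE_CODES
from .terrain import ASPECT_CODES

log = logging.getLogger(__name__)

#: Column order of the site-characteristics summary (means per zone).
MEAN_COLUMNS = ("elevation", "slope", "insolation", "awc", "depth", "ph",
                "gdd", "bedd", "ffd", "gsp")

ASPECT_CATEGORIES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW", "Flat")


def _zone_cell_mask(grid: Grid, geom) -> np.ndarray:
    X, Y = grid.cell_centers()
    return shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(grid.shape)


def zonal_mean(grid: Grid, zones: ZoneSet) -> dict[str, float]:
    """Arithmetic mean per zone over data cells with centers in the polygon.

    Zones whose intersection with the grid holds no data cells are omitted
    with a warning.
    """
    if zones.crs_tag is not None and zones.crs_tag != grid.crs_tag:
        raise ValueError(f"CRS mismatch: grid {grid.crs_tag}, zones {zones.crs_tag}")
    vals = grid.data()
    out: dict[str, float] = {}
    for zid, geom in zones.zones:
        cells = vals[_zone_cell_mask(grid, geom)]
        cells = cells[np.isfinite(cells)]
        if cells.size == 0:
            log.warning("zonal_mean: zone %s has no data cells; omitted", zid)
            continue
        out[zid] = float(cells.mean())
    return out


def zonal_class_proportions(
    class_grid: Grid, zones: ZoneSet, classes: tuple | None = None
) -> dict[str, dict]:
    """Per-zone fraction of data cells in each category of a coded grid.

    Classes absent from a zone are reported as 0; ``classes`` fixes the keys
    (integer codes) reported, defaulting to the codes present anywhere.
    """
    if zones.crs_tag is not None and zones.crs_tag != class_grid.crs_tag:
        raise ValueError("CRS mismatch between class grid and zones")
    vals = class_grid.data()
    if classes is None:
        present = vals[np.isfinite(vals)]
        classes = tuple(sorted({int(v) for v in present}))
    out: dict[str, dict] = {}
    for zid, geom in zones.zones:
        cells = vals[_zone_cell_mask(class_grid, geom)]
        cells = cells[np.isfinite(cells)]
        if cells.size == 0:
            log.warning("zonal_class_proportions: zone %s has no data cells; omitted", zid)
            continue
        out[zid] = {c: float(np.mean(cells == c)) for c in classes}
    return out


def summarize_zones(
    layers: dict[str, Grid],
    zones: ZoneSet,
    drainage: Grid | None = None,
    aspect_class: Grid | None = None,
) -> pd.DataFrame:
    """One summary row per zone: layer means plus class proportions.

    ``layers`` must provide every name in :data:`MEAN_COLUMNS`; ``drainage``
    and ``aspect_class`` are integer-coded grids whose per-zone fractions are
    appended as ``drainage_<CLASS>`` and ``aspect_<SECTOR>`` columns.  Rows
    follow the order of ``zones``; each proportion block sums to 1 per zone.
    """
    missing = [name for name in MEAN_COLUMNS if name not in layers]
    if missing:
        raise ValueError(f"missing layers: {missing}")
    records: dict[str, dict] = {zid: {} for zid in zones.zone_ids}
    for name in MEAN_COLUMNS:
        means = zonal_mean(layers[name], zones)
        for zid in records:
            records[zid][name] = means.get(zid, np.nan)
    if drainage is not None:
        codes = tuple(DRAINAGE_CODES[c] for c in DRAINAGE_CLASSES)
        props = zonal_class_proportions(drainage, zones, classes=codes)
        for zid in records:
            p = props.get(zid, {})
            for cls in DRAINAGE_CLASSES:
                records[zid][f"drainage_{cls}"] = p.get(DRAINAGE_CODES[cls], np.nan)
    if aspect_class is not None:
        codes = tuple(ASPECT_CODES[c] for c in ASPECT_CATEGORIES)
        props = zonal_class_proportions(aspect_class, zones, classes=codes)
        for zid in records:
            p = props.get(zid, {})
            for cat in ASPECT_CATEGORIES:
                records[zid][f"aspect_{cat}"] = p.get(ASPECT_CODES[cat], np.nan)
    df = pd.DataFrame.from_dict(records, orient="index")
    df.index.name = "zone"
    return df.loc[zones.zone_ids]


@dataclass
class ContrastReport:
    """Signed pairwise zone differences plus cross-variable rankings."""

    variable: str
    differences: dict[tuple[str, str], float]
    rankings: dict[str, list[str]] = field(default_factory=dict)
    gdd_bedd_gap: dict[str, float] = field(default_factory=dict)


def _variable_series(summaries: pd.DataFrame, variable: str) -> pd.Series:
    if variable == "gdd_bedd_gap":
        return summaries["gdd"] - summaries["bedd"]
    if variable not in summaries.columns:
        raise KeyError(f"unknown variable {variable!r}")
    return summaries[variable]


def contrast(
    summaries: pd.DataFrame,
    pairs: list[tuple[str, str]],
    variable: str,
) -> ContrastReport:
    """Signed differences ``value(a) - value(b)`` for named zone pairs.

    ``variable`` may be any summary column or the derived ``gdd_bedd_gap``
    (GDD minus BEDD).  Differences are antisymmetric and vanish on the
    diagonal; rankings (descending) are reported for every numeric column.
    """
    series = _variable_series(summaries, variable)
    for a, b in pairs:
        for z in (a, b):
            if z not in summaries.index:
                raise KeyError(f"unknown zone {z!r}")
    diffs = {(a, b): float(series[a] - series[b]) for a, b in pairs}
    rankings = {
        col: list(summaries[col].sort_values(ascending=False).index)
        for col in summaries.columns
        if pd.api.types.is_numeric_dtype(summaries[col])
    }
    gap = {}
    if "gdd" in summaries.columns and "bedd" in summaries.columns:
        gap = (summaries["gdd"] - summaries["bedd"]).to_dict()
        rankings["gdd_bedd_gap"] = list(
            (summaries["gdd"] - summaries["bedd"]).sort_values(ascending=False).index
        )
    return ContrastReport(variable, diffs, rankings, gap)


def column_average(summaries: pd.DataFrame, variable: str) -> float:
    """Unweighted mean of one summary column across zones.

    Zones with a missing entry for the column are excluded from the mean,
    matching how summary tables with absent classes average their rows.
    """
    series = _variable_series(summaries, variable)
    if series.dropna().empty:
        raise ValueError(f"no data for variable {variable!r}")
    return float(series.mean(skipna=True))
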