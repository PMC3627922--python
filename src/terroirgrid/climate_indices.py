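"""Growing-season heat, frost and precipitation surfaces from monthly normals.

All indices run over the Northern-Hemisphere growing season, April-October:

* GDD (growing degree-days, C-degrees): sum over months of
  ``max(0, tavg - 10) * days_in_month`` — monthly-normal form of the classic
  base-10 heat summation used to rate wine-grape climates.
* BEDD (biologically effective degree-days): the same summation with the mean
  daily rate capped at 9 C-degrees, reflecting the 10-19 degC window in which
  *Vitis vinifera* development is most active; BEDD <= GDD everywhere.
* FFD (frost-free days): first-fall minus last-spring median frost day of
  year; a proxy for growing-season length.
* GSP (growing-season precipitation, mm): April-October sum; a proxy for
  powdery-mildew pressure.

Nodata in any input propagates to nodata in the derived surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids_io import Grid

log = logging.getLogger(__name__)

#: Growing-season months and their day counts (leap years irrelevant: Apr-Oct).
SEASON_MONTHS = (4, 5, 6, 7, 8, 9, 10)
DAYS_IN_MONTH = {4: 30, 5: 31, 6: 30, 7: 31, 8: 31, 9: 30, 10: 31}
SEASON_DAYS = sum(DAYS_IN_MONTH.values())  # 214

GDD_BASE = 10.0  # degC
BEDD_CAP = 9.0  # C-degrees per day


@dataclass
class MonthlyNormals:
    """April-October monthly normal grids plus median frost-date surfaces.

    ``tmax``/``tmin`` in degC, ``ppt`` in mm, frost dates as day of year.
    """

    tmax: dict[int, Grid]
    tmin: dict[int, Grid]
    ppt: dict[int, Grid]
    last_spring_frost: Grid
    first_fall_frost: Grid

    def __post_init__(self) -> None:
        for name, d in (("tmax", self.tmax), ("tmin", self.tmin), ("ppt", self.ppt)):
            missing = [m for m in SEASON_MONTHS if m not in d]
            if missing:
                raise ValueError(f"{name} missing months {missing}")
        ref = self.tmax[4]
        for d in (self.tmax, self.tmin, self.ppt):
            for g in d.values():
                ref.assert_aligned(g)
        ref.assert_aligned(self.last_spring_frost)
        ref.assert_aligned(self.first_fall_frost)
        for m in SEASON_MONTHS:
            hi, lo = self.tmax[m].data(), self.tmin[m].data()
            both = np.isfinite(hi) & np.isfinite(lo)
            if np.any(hi[both] < lo[both]):
                raise ValueError(f"tmax < tmin in month {m}")

    @property
    def reference(self) -> Grid:
        return self.tmax[4]


@dataclass
class ClimateSurfaces:
    """Derived climate-index grids."""

    gdd: Grid
    bedd: Grid
    ffd: Grid
    gsp: Grid


def monthly_mean_temperature(tmax: Grid, tmin: Grid) -> Grid:
    """Cell-wise (tmax + tmin) / 2."""
    tmax.assert_aligned(tmin)
    return tmax.with_values((tmax.data() + tmin.data()) / 2.0)


def growing_degree_days(normals: MonthlyNormals, base: float = GDD_BASE) -> Grid:
    """Base-``base`` degree-day accumulation over April-October.

    Monthly contributions are clamped at zero before summation — heat deficits
    in cool months do not cancel accumulation in warm ones.
    """
    ref = normals.reference
    total = np.zeros(ref.shape)
    for m in SEASON_MONTHS:
        tavg = monthly_mean_temperature(normals.tmax[m], normals.tmin[m]).data()
        total += np.maximum(0.0, tavg - base) * DAYS_IN_MONTH[m]
    g = ref.with_values(total)
    g.meta = {"layer": "gdd_c"}
    return g


def biologically_effective_degree_days(
    normals: MonthlyNormals, base: float = GDD_BASE, cap: float = BEDD_CAP
) -> Grid:
    """GDD with the mean daily rate capped at ``cap`` C-degrees per day."""
    ref = normals.reference
    total = np.zeros(ref.shape)
    for m in SEASON_MONTHS:
        tavg = monthly_mean_temperature(normals.tmax[m], normals.tmin[m]).data()
        total += np.minimum(cap, np.maximum(0.0, tavg - base)) * DAYS_IN_MONTH[m]
    g = ref.with_values(total)
    g.meta = {"layer": "bedd_c"}
    return g


def frost_free_days(last_spring: Grid, first_fall: Grid) -> Grid:
    """First-fall minus last-spring frost day of year.

    Cells where the recorded fall frost precedes the spring frost are
    physically inconsistent: they are flagged nodata and counted in a warning.
    """
    last_spring.assert_aligned(first_fall)
    diff = first_fall.data() - last_spring.data()
    negative = diff < 0
    n_bad = int(np.count_nonzero(negative))
    if n_bad:
        log.warning("frost_free_days: %d cells with fall frost before spring frost "
                    "set to nodata", n_bad)
        diff[negative] = np.nan
    g = last_spring.with_values(diff, extra_mask=negative)
    g.meta = {"layer": "ffd_days"}
    return g


def growing_season_precipitation(normals: MonthlyNormals) -> Grid:
    """April-October precipitation sum in mm."""
    ref = normals.reference
    total = np.zeros(ref.shape)
    for m in SEASON_MONTHS:
        total += normals.ppt[m].data()
    g = ref.with_values(total)
    g.meta = {"layer": "gsp_mm"}
    return g


def compute_climate_surfaces(
    normals: MonthlyNormals, base: float = GDD_BASE, cap: float = BEDD_CAP
) -> ClimateSurfaces:
    """All four climate-index surfaces in one call."""
    return ClimateSurfaces(
        gdd=growing_degree_days(normals, base),
        bedd=biologically_effective_degree_days(normals, base, cap),
        ffd=frost_free_days(normals.last_spring_frost, normals.first_fall_frost),
        gsp=growing_season_precipitation(normals),
    )
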