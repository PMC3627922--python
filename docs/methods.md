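# Methods

## Data model and conventions

All analysis runs on `Grid`: a single-band 2-D float array in a projected,
metric, north-up coordinate system (row 0 at the northern edge), with an
affine transform (origin, cell width, negative cell height) and an explicit
boolean nodata mask. Nodata in any input propagates to nodata in every
derived layer at that cell. All stages require their inputs pre-aligned to a
common grid and raise on mismatched transforms or CRS tags; reprojection and
warping are out of scope — inputs are expected to arrive already projected
(e.g. to UTM).

Membership of a raster cell in a polygon — for water masking, soil
rasterization and zonal statistics alike — is by **cell-center containment**.
This is the common zonal-statistics convention and is exactly testable
against a point-in-polygon oracle; partially covered cells are counted
entirely in or entirely out. Water polygons are masked to nodata before
summarization, and the operation is idempotent.

GeoTIFF I/O stores values as float64 with NaN at nodata (advertised via the
GDAL_NODATA tag) so finite values, transform and mask round-trip losslessly;
georeferencing travels in the standard ModelPixelScale/ModelTiepoint/GeoKey
tags with the EPSG code. Vector inputs are GeoJSON; invalid (self-crossing)
polygons are repaired by default or rejected via a flag.

Resampling is bilinear for continuous layers and nearest-neighbor for
categorical ones. Nodata is never interpolated across: an output cell whose
bilinear stencil touches any nodata cell becomes nodata.

## Terrain

Slope and aspect use Horn's 3×3 weighted finite differences — the default of
the mainstream GIS packages, so outputs are comparable with standard layers;
a Zevenbergen–Thorne variant would change interior values only marginally
and was not needed. Slope is reported in percent rise; aspect is the compass
bearing of the negative gradient. Cells with exactly zero gradient receive a
flat sentinel and their own category; flat is never folded into north.
Aspect sectors are 45° wide, centered on the cardinal/intercardinal
directions, left-closed/right-open (337.5° classifies as N). Edges use
replication; any nodata within the 3×3 stencil makes the output cell nodata.

## Solar model

The insolation surface is a hemispherical-viewshed clear-sky model intended
as a *comparative index of topographic exposure*, not a measured-radiation
climatology; absolute magnitudes depend on the transmissivity assumption and
the lattice discretization.

- **Horizon angles.** For each cell and each of 32 azimuths, rays are
  sampled at one-cell steps to a configurable radius with bilinear DEM
  interpolation; the horizon is the maximum elevation angle encountered
  (0 if unobstructed). Samples beyond the DEM are ignored.
- **Sun positions.** A lattice over ordinal days 91–304 at 14-day steps and
  2-hour steps (16 days × up to 12 hours). Declination uses the Cooper
  approximation (23.45°·sin(2π(284+n)/365)); sub-degree accuracy is
  sufficient because the output is a seasonal accumulation used
  comparatively. Positions below the astronomical horizon are dropped.
- **Direct beam.** S₀·τ^m per position, with S₀ = 1367 W/m², default
  τ = 0.5, and relative optical air mass m = e^(−0.000118·elev)/cos θ_z.
  The beam reaches a cell when the sun stands above the interpolated horizon
  at its azimuth, contributing cos(incidence) on the sloped facet (negative
  incidence contributes zero) times the 14-day × 2-hour block.
- **Diffuse.** A uniform sky split into 8 zenith × 8 azimuth sectors. Each
  sector contributes its *unobstructed* solid angle (the gap fraction is
  resolved on the azimuth discretization implied by the 40,000-cell
  hemisphere raster, i.e. 200 azimuth columns) times incidence on the facet.
  The magnitude is normalized so that an unobstructed horizontal cell
  receives exactly the configured diffuse proportion (default 0.3) of global
  radiation; a fully obstructed cell receives zero of either component.
- **Latitude banding.** Sun positions are evaluated at a single mean
  latitude per raster. Tall rasters are split into north–south bands whose
  span stays below a configurable latitude extent, each band carrying its
  own mean latitude and an overlap strip (default: the horizon radius);
  outputs are mosaicked with a linear weight ramp across the strip, so the
  blend is a convex combination and equals the unique tile elsewhere. On a
  100×100 composite DEM the tiled result agrees with a single pass to well
  under 1% outside a band around the strip edges (horizon truncation at
  internal tile edges is the residual, which the overlap is sized to absorb).

## Climate indices

Indices are computed from April–October monthly normals, the season over
which degree-days for *V. vinifera* are conventionally accumulated; monthly
day counts are fixed (30, 31, 30, 31, 31, 30, 31 = 214 days; leap years are
irrelevant to this window). Monthly contributions to GDD are clamped at zero
before summation — a heat-accumulation index cannot go negative and cool
months must not cancel warm ones. The BEDD cap is applied to the monthly
mean daily rate, min(9, max(0, T̄−10))·d_m, the only construction available
from monthly normals; consequently BEDD ≤ GDD cell-wise, with equality
wherever every monthly mean stays at or below 19 °C. Frost-date surfaces are
consumed as given (day-of-year grids); cells whose recorded fall frost
precedes the spring frost are physically inconsistent and are flagged nodata
with a logged count. Degree-day surfaces built from monthly normals read
systematically cooler than station daily summations; no reconciliation is
attempted.

## Soils

The survey model carries the minimal SSURGO slice the thematic maps need:
map-unit polygons, components (area percent, drainage class, restrictive
depth) and horizons (depth interval, AWC, pH). Aggregation is **dominant
component** — the component with the largest area percent, ties broken by
lexicographically smallest component key so results are deterministic; a
dominant-condition alternative (percents summed over components sharing a
drainage class) is available for categorical maps. Profile attributes are
thickness-weighted over 0–50 cm, the layer from which vines draw most
nutrition; horizons missing a value are dropped from numerator and
denominator, and no coverage yields an absent value. A missing restrictive
depth is censored to 200 cm, the conventional survey depth. Rasterization at
10 m (configurable) assigns each cell its containing map unit's aggregated
value; drainage classes are coded 1–7 (ED…VPD) with a sidecar legend.

## Zonal summaries and contrasts

Zone means are arithmetic means over data cells whose centers fall in the
zone polygon (water already masked); zones with no data cells are omitted
with a warning rather than reported as zero. Class proportions are cell
fractions among a zone's data cells and sum to 1 per zone. Cross-zone column
averages are unweighted by area and skip missing entries — so a class absent
from some appellations is averaged over the appellations that have it.
Contrasts are signed differences of any summary variable, or of the derived
GDD−BEDD gap; they are antisymmetric and vanish on the diagonal. Values are
kept at full precision internally and rounded only at serialization.

## PCA

The stack is fixed at seven layers — elevation, AWC, pH, depth, GDD, FFD,
GSP — in that order. Slope, aspect and insolation are DEM-derived (adding
them would double-count elevation information), drainage class is
categorical, and BEDD is derived from the same normals as GDD with reduced
variability, so all five are excluded. Each layer is z-scored over the
common mask (population SD by default; the sample/population choice is
configurable and immaterial at raster n, but pinned for reproducibility);
a constant layer has no z-score and is rejected by name. The covariance
matrix of the standardized stack — equivalently the correlation matrix of
the raw layers — is eigen-decomposed; eigenvalues are sorted descending and
each eigenvector is sign-fixed so its largest-magnitude component is
positive, making loadings unique and runs deterministic. Variance fractions
are eigenvalue shares of the trace. The full mask is used; no cell thinning.

## Synthetic fixtures

The generators emulate the statistical structure of the real input archives
at desk scale: analytic DEMs (plane with known gradient, Gaussian hill,
incised valley, composite), monthly normals coupled to elevation by a linear
lapse rate (default −6.5 °C/km) with a fixed diurnal range (12 °C, so
tmax ≥ tmin by construction), precipitation increasing with elevation
(+50 mm/km across the season), frost dates tightening by 3 days per 100 m
with fall ≥ spring enforced, additive Gaussian noise per variable, Voronoi
map units with 1–3 components (integer percents summing to 100) and 2–4
horizons of plausible AWC (0.05–0.25 cm/cm) and pH (5.5–8.5), and
rectangular zone strips with an optional water body. Every generator is a
pure function of (config, seed), and analytic ground truth (gradients,
dominant components, weighted attributes) is recorded in metadata for oracle
tests.

What the fixtures do *not* emulate: spatial autocorrelation of climate
residuals, orographic/rain-shadow asymmetries, the regression machinery of
real climate mapping, realistic soil geography or categorical structure.
Passing tests therefore demonstrate that the *operations* are correct
(against closed forms, brute-force oracles and the shipped reference
tables), not that the pipeline reproduces any real region's surfaces from
raw archives — that reproduction requires the real elevation, climate-normal
and soil-survey inputs plus digitized appellation boundaries, and is
documented as an external exercise.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately small grids: 8×8 flat cells for
solar oracle agreement, a 100×100 DEM for the tiling/mosaic comparison,
10,000 cells for the PCA equal-share check, 50×60 fixtures with 5–6 zones
for the end-to-end recoveries. These sizes make every check exact or
tight (slope/aspect to 1e−9 of closed forms, eigen-reconstruction to 1e−8
Frobenius, zonal means to 1e−12 of the membership oracle) while keeping the
full suite in seconds. Tolerances that are not exact identities reflect
discretization, not fitting: 0.5% for the solar oracle (interpolation of
horizon angles), 1% for the mosaic (per-band latitude and edge truncation),
±0.02 on 1/7 variance shares at n = 10,000 (sampling noise), 5% for
lapse-rate recovery at 0.1 °C noise.

## Known limitations

- No reprojection: inputs must share one projected CRS and grid.
- Solar magnitudes are comparative; no cloud climatology, measured-radiation
  calibration or longwave exchange, and no attempt to match any particular
  GIS implementation's sector-weighting constants.
- Horizon rays interpolate bilinearly at one-cell steps; very thin obstacles
  between sample points can be under-resolved.
- Degree-days from monthly normals, not daily records; median frost-date
  derivation is upstream of this package.
- Shapefile input is not supported; use GeoJSON.
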