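# Methods

This note documents the models, parameter choices and numerical decisions
behind `isovel`, and what the synthetic experiments do and do not show.

## The two lapse-rate models

**Moist adiabatic rate (MALRT).**  A saturated air parcel rising along a
slope cools at

```
Γ_w = g · (1 + H_v γ / (R_sd T)) / (C_pd + H_v² γ ε / (R_sd T²))   [K/m]
```

with `γ = ε e / (p − e)` the mixing ratio of water-vapour mass to dry-air
mass.  Constants (SI): g = 9.8076 m/s², H_v = 2,501,000 J/kg,
R_sd = 287 J/(kg·K), ε = 0.622, C_pd = 1005 J/(kg·K).  Output is converted
to °C/km (×1000).  The dry limit (e = 0) is g/C_pd = 9.76 °C/km, an upper
bound attained only in perfectly dry air; the rate decreases strictly with
vapour pressure, which the tests verify numerically on a
T ∈ [250, 310] K × e ∈ [0, 4000] Pa lattice.  Note that at *fixed* e and p
the formula increases mildly with T over terrestrial ranges; the often-
stated "warmer air → shallower lapse" refers to the covariation of e with
T across real climates (warm air holds more vapour), so only the
e-monotonicity is asserted as an invariant.

Air pressure comes from the isothermal barometric formula
`p = p0 · exp(−g h / (R_sd T))` with p0 = 101,325 Pa and the cell's own
mean annual temperature — a deliberate simplification (no lapse inside the
column); the constants object is swappable for a polytropic variant.
Gridded inputs are mean annual temperature in °C (converted to K) and
vapour pressure in hPa (converted to Pa).  When only relative humidity is
available, `saturation_vapour_pressure` (Magnus form, valid 180–340 K;
611.2 Pa at 0 °C) converts it to vapour pressure.

**Terrain-transect rate (SLRT).**  For every coarse (0.5°) cell, the
surrounding 1.5° × 1.5° window of the fine (0.05°) DEM is scanned for
regional peaks and foothills; transects join each peak to its nearest
foothill and vice versa; temperature is regressed on elevation over every
fine cell the straight segment touches; slopes passing R² ≥ 0.5 and
P ≤ 0.05 (t test, n − 2 df) and n ≥ 3 are kept; the cell's SLRT is
−1000 × (median slope) when more than 10 transects intersect it, the mean
otherwise.  Positive SLRT means temperature falls with height; negative
values are inversions.

Three parts of this procedure are design choices where the method leaves
room:

- *Feature rule*: strict 8-neighbourhood extrema with topographic
  prominence ≥ 100 m (configurable).  Prominence is computed exactly by a
  descending flood with a union–find: when two summit components merge at
  level v, the lower summit's prominence is its height above v; the
  window's top summit is measured against the window minimum.  Equal-
  valued plateau extrema collapse to the lowest row-major representative.
  The 100 m default suppresses pixel noise while keeping regional relief;
  the unit tests check the implementation against an independent
  label-and-flood oracle.
- *Pairing*: symmetric nearest-neighbour (planar grid distance, ties to
  the lower row-major index), deduplicated — the minimal reading of
  "nearest features".
- *Rasterisation*: supercover — every cell whose closed footprint the
  segment intersects belongs to the transect, including corner grazes.
  Implemented with exact integer arithmetic (coordinates doubled so edges
  fall on odd integers; separating-axis test per candidate cell) and
  cross-checked against a `shapely` intersection oracle.

Windows at grid edges are cropped, not padded; the moving-window stride is
one coarse cell; regression cells are unweighted by intersection length.

## Velocities, exposure, and summaries

`v = 1000 · rate / lapse` (m/yr), with the warming rate taken as the
difference of two decadal mean-annual-temperature climatologies divided by
the 40-year span between them.  A constant 5.5 °C/km lapse serves as the
control method.  Zero-lapse cells become nodata (with a counted warning);
*near*-zero lapse cells are deliberately not masked here — the exposure
stage removes the lowest 1% of |SLRT| (exactly ⌊fraction · n⌋ cells by
rank, ties broken by scan order) before thresholding, mirroring the
outlier handling of the analysis this package operationalises.

Exposure thresholds are per-method q-quantiles (linear interpolation,
q = 0.8 default, 0.9 variant) of each map's own finite velocities; cells
strictly above a threshold "fire" for that method, and the categorical map
records none/one/both.  Union-mode flagged fractions therefore lie in
[1 − q, 1 − q²] up to quantile ties.  Signed velocities are thresholded by
default (upslope risk); an absolute-value mode exists.

The elevation–latitude summaries use half-open bins anchored at 0 m and
the equator (250 m × 2° defaults).  The plane regression is an OLS of
cell velocity on elevation (km), |latitude| (deg) and hemisphere (Northern
reference; an exactly-equatorial cell centre counts as Northern) with all
interactions; with single-hemisphere data the hemisphere terms are
dropped rather than reported as 0/NaN, and genuine collinearity raises an
error naming the offending columns.  Group contrasts (mainland/island ×
hemisphere) use one-way ANOVA plus Tukey HSD via `statsmodels`.

## Station validation

A station qualifies in a year when **more than 10** months are recorded
(i.e. ≥ 11), and is retained when **at least 8** years of 2011–2019
qualify — the strict reading of "more than eight years / more than 10
months"; its mean annual temperature averages qualifying years only.
Every coarse cell containing a station seeds a 3×3-cell "mountain site";
identical station sets are deduplicated.  A site's LRT is −1000 × the OLS
slope of station mean annual temperature on elevation, undefined below 3
distinct elevations.  Validation regresses site LRTs on each gridded
map's value at the site centre, after removing sites beyond 3 median
absolute deviations from the median site LRT — a reproducible replacement
for ad-hoc "two extreme outliers" removal; excluded site ids are reported.

## Tracking probability

Each range-shift record (taxon group, region, centroid, study extent,
shift velocity in m/yr) is paired with the isotherm velocity of the map
cell containing its centroid — the paired-test reading of the signed-rank
comparison; studies wider than 1° in either extent dimension are dropped
so one centroid velocity can represent them.  Per taxon × region group:
1,000 iterations each resample 30 records **without replacement** (all
records when fewer exist), test `shift − velocity` with the two-tailed
Wilcoxon signed-rank test, and the tracking probability is the fraction of
iterations with p ≥ α = 0.05.  One root seed spawns per-iteration seed
sequences, so any single iteration is reproducible and the resampled index
sets depend only on (seed, record count) — which is what makes the
probability provably non-increasing in a constant tracking deficit at a
fixed seed schedule.

The signed-rank test drops zero differences (p = 1 when all are zero),
mid-ranks ties, and uses the exact null distribution of the positive-rank
sum (generating-polynomial enumeration) for n ≤ 25 without ties, else the
normal approximation with continuity and tie corrections; it is
cross-checked against `scipy.stats.wilcoxon` in both regimes.  The probit
curve `P = Φ(a + b·|v|)` is an unweighted binomial GLM with probit link on
the per-group proportions (weighting by record count is a documented
alternative the data did not require).

## Synthetic study conditions

The generators emulate the statistical structure the pipeline assumes, on
a desk-scale domain: a 3° × 3° region at 0.05° resolution (60 × 60 fine
cells, 6 × 6 coarse), terrain built from 8 Gaussian peaks (1500–3000 m,
σ = 2–4 cells) **and 8 Gaussian valley depressions** (250–450 m) over a
500 m base — the valleys matter, because a bump-only surface over a flat
plain has almost no 100 m-prominent foothills and hence almost no
transects — plus 10 m of correlated noise.  Temperature is
`T = T0 − Γ·z/1000 + N(0, 0.05 °C)` with Γ = 6.5 °C/km (the reference true
lapse) and a flat sea-level T0 = 15 °C by default (a latitudinal gradient
is available but off, so transect slopes estimate Γ without a latitude
confound).  Warming is 1 °C between the two decades (0.025 °C/yr); vapour
is 10 hPa at sea level declining with a 2,500 m e-folding height.  Station
networks (25 stations, 20% with only 10 recorded months per year, to
exercise the filter), island masks (20% of cells) and range-shift tables
(210 records, 7 taxa, 30% of studies wider than 1°, configurable tracking
deficit and 1 m/yr shift noise) complete the inputs.  Every generator is a
pure function of (scenario, seed) via named, stably-derived substreams.

**What passing tests show — and don't.**  Gaussian noise everywhere, no
cloud-gap patterns, no realistic orography spectra, no spatially
correlated temperature error, and a spatially uniform true lapse rate.
Parameter recovery and calibration on these conditions demonstrate the
estimators are unbiased and the resampling test is calibrated; they do not
demonstrate robustness to the error structures of real satellite or
station data.  On the small domain only a few coarse cells accumulate more
than ten transects, so the median aggregation path is exercised mainly by
direct unit tests.

## Numerical choices and limitations

- Aggregation ignores NaN within blocks (a coarse cell is missing only if
  its whole block is); cell-wise arithmetic propagates NaN.  Latitude
  bands are *not* area-weighted — a documented limitation of the
  geographic-grid design.
- Quantiles are linear-interpolation throughout, for bit-reproducibility.
- GeoTIFF I/O writes the standard georeferencing tags (pixel scale, tie
  point, WGS84 geokeys, GDAL nodata) via `tifffile`; NetCDF uses the
  classic format via `xarray`'s scipy engine.  No reprojection: grids are
  geographic (WGS84), cell-centre convention, rows increasing southward.
- The pipeline (`isovel all`) runs the full synthetic chain in a few
  seconds and is byte-reproducible for a fixed seed; problem sizes in the
  tests (60 × 60 fine grids, ≤ 1,000 resampling iterations, ≤ 40
  replicates per calibration check) were chosen so the whole suite stays
  lightweight while keeping Monte-Carlo error well inside the asserted
  tolerances.
- Out of scope by design: ingesting the real global satellite/climate/
  station/range-shift archives, island delineation from 30 m DEMs, manual
  delineation of named threatened regions, and horizontal (spatial-
  gradient) climate velocities.
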