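# Methods

This note documents the models and procedures implemented in `middensdm`,
the parameters that matter, and what the synthetic experiments do and do
not demonstrate.

## Problem setting

Red squirrel middens are durable, visually conspicuous cone caches; a
near-complete midden census over a small study area can stand in for
territory occupancy. The package models midden occurrence at 3 × 3 m
resolution as a function of forest structure (LIDAR-derived canopy height
and density, terrain slope/aspect/elevation) and human disturbance
(Euclidean distance to lake, recreational trails, a winter dog trail, a
highway and buildings). The modelled quantity is a relative index of
occurrence (RIO) in [0, 1] — a ranking score for habitat suitability, not
a calibrated detection probability, because presence/pseudo-absence
training with class re-weighting destroys calibration on purpose.

## Raster conventions

All rasters are planar, north-up, square-cell grids: row 0 is the
northernmost row, the origin is the outer north-west corner, and cell
membership is half-open (a point on a shared edge belongs to the cell to
its east/south), so every point or LIDAR return is counted exactly once.
No-data is NaN in memory and a sentinel (−9999) on disk. Coordinates are
planar meters with a carried-through CRS tag; the package never
reprojects. Rasters are exchanged as ESRI ASCII grids with a JSON sidecar
(variable name, units, CRS), vectors as GeoJSON, and point clouds as a
plain `x,y,z,class` CSV with class in {ground, vegetation, unclassified} —
deliberately text-only formats so runs are diffable and portable.

## Predictor derivation

* **Vegetation merge.** Provider-classified clouds leave part of the
  vegetated returns unclassified; all unclassified returns are relabeled
  vegetation before gridding (idempotent, count-preserving).
* **DEM** — per-cell mean z of ground returns. The mean (rather than
  minimum or a TIN) is robust at the ~7–8 ground returns per 3 m cell the
  default point spacing produces. Cells without ground returns are
  no-data, then filled by inverse-distance weighting from the k = 8
  nearest filled cells; filled values are convex combinations of donors.
* **Canopy density** — vegetation returns / all returns per cell, in
  [0, 1]; empty cells gap-filled as above.
* **Canopy height** — max z of vegetation returns minus the cell's DEM
  value, floored at 0; cells without vegetation returns are 0. The DEM
  subtraction makes the layer above-ground height, which is what a
  height-threshold response (see below) is defined on.
* **Slope/aspect** — Horn's 3 × 3 finite differences with
  replicated-border padding. Slope = atan(|∇z|) in degrees. Aspect is the
  compass azimuth of steepest *descent*, clockwise from north in
  [0, 360); a plane rising due east (dz/dx = 1) has slope 45° and aspect
  270° (descending west). Flat cells carry the sentinel −1. Aspect is fed
  to the trees as raw degrees — no circular encoding — mirroring how a
  GIS-exported aspect layer is typically consumed; the 0/360 wrap is a
  known limitation the trees must spend extra splits on.
* **Distance layers** — the feature class is rasterized (any cell whose
  square intersects the geometry is a source cell) and each cell takes
  the exact Euclidean distance from its center to the nearest source-cell
  center (`scipy.ndimage.distance_transform_edt`). This is raster-GIS
  "Euclidean distance" semantics; it differs from exact
  distance-to-geometry by at most one cell diagonal.

## Training data

Presences are the midden points; pseudo-absences are points uniform over
the study-area polygon (rejection sampling, seeded). No minimum-distance
exclusion between absences and presences is applied by default — random
background points are used as-is, which is the standard design when the
presence census is believed near-complete — but a `min_dist` option
exists. Predictor values are extracted by containing-cell lookup (no
interpolation). Balancing weights give each class equal total weight:
absence weight 1, presence weight n₀/n₁.

## The boosted-tree model

A stochastic gradient-boosted ensemble of depth-limited regression trees
with a logistic link, trained on binomial deviance with Newton leaf steps
(the TreeNet/MART family). Parameters, with defaults and rationale:

| parameter | default | role |
|---|---|---|
| `n_trees` | 400 | ensemble size; generic default for this family |
| `max_depth` | 10 | maximum tree depth (deep trees, interactions) |
| `min_leaf` | 2 | minimum unweighted samples per leaf |
| `shrinkage` | 0.01 | learn rate ν; small and safe with 400 trees |
| `subsample` | 0.5 | row fraction per tree, without replacement |
| `seed` | 0 | all stochasticity (subsampling) |

Shrinkage and subsampling are the two knobs a commercial implementation
would hide behind "default settings"; they are therefore always logged in
the run manifest. Split search is exact greedy (all features, midpoints
between sorted distinct values, maximizing weighted SSE reduction of the
residuals), with ties broken toward the lowest feature index and then the
lowest threshold, so a fit is a pure function of (table, config). With
subsample = 1 the training deviance is provably non-increasing, and the
test suite asserts it; with subsampling it is non-increasing only in
expectation.

Variable importance is the per-feature sum of split improvements across
all trees, rescaled so the maximum is 100.00. Partial dependence is
computed by brute force — mean raw score over the training rows with the
feature forced to each grid value — and reported on the centered log-odds
scale, so only its shape and sign structure are interpretable, not its
level. ROC AUC is the weighted Mann–Whitney statistic
P(s₁ > s₀) + ½P(tie), computed on the training set (internal AUC); it is
an optimistic estimate by construction and is reported as such.

## Surface, occupancy, abundance

The prediction lattice defaults to the predictor cell centers (3 m
spacing), so IDW interpolation (power 2, k = 12; a cell coinciding with a
point takes its value exactly) is near-identity; coarser lattices make the
IDW smoothing meaningful. The occupancy threshold is the nearest-rank
lower 5th percentile of the presence RIOs: t = k-th smallest with
k = ⌈0.05·N⌉, which retains a presence fraction in [0.95, 0.95 + 1/N]
for continuous values (ties can only push it higher). Occupancy uses the
closed bound (RIO ≥ t).

Abundance arithmetic is exact rational arithmetic with half-up rounding
only at reporting: density = n/area, territory = area/n,
population ∈ [⌊n/(1+max_secondary)⌋, n]. `max_secondary = 3` reflects the
upper range of secondary-midden counts reported for this species; it is a
free assumption, not an estimate, and the population bounds should be
read as bracketing, not as confidence limits. Validation extracts the RIO
at an independent presence set and reports min/Q1/mean/Q3/max (type-7
quartiles) plus the fraction of points strictly above the mean scored-
lattice value — the better-than-random check.

## Synthetic landscape generator

The generator emulates the descriptive statistics of the reference site:
an 880 × 850 m bounding box gridded at 3 m (truncated to whole cells,
879 × 849 m), elevation spanning 145–190 m, canopy heights up to 25 m,
LIDAR point spacing 0.82 m (2.7 ft) with ground-return vertical noise
σ = 0.04 m, 30% of vegetation returns left "unclassified", five vector
feature classes (lake in the north, highway along the west edge, a trail
network, a dog trail, buildings near the east edge), and a 45.5 ha
study-area polygon.

Terrain and canopy are Gaussian-smoothed white noise (bandwidths 60 m and
25 m), rescaled to their ranges; canopy height and density are positively
correlated by construction and an open-meadow patch is zeroed in both.
Vegetation returns are Poisson per cell with expectation
`8 × density`, z uniform in (ground, ground + canopy height].

Midden presence is a cell-wise Bernoulli draw with
logit p = intercept + Σ responses, where the responses are
piecewise-linear threshold shapes: positive above 9 m canopy height,
negative within 10 m of trails (positive to ~30 m, a dip at 30–50 m),
negative below 0.45 canopy density, positive within 250 m of the lake.
The intercept is calibrated by bisection so the expected presence count
over the study polygon is 198; the <10 m diffuse-midden merge rule
(greedy thinning in deterministic y-descending, x-ascending order) is
applied afterwards, so realized counts run ~175–185. An independent,
smaller draw (expected 25–30 points) emulates an opportunistic validation
survey.

What the generator does *not* emulate: spatial interaction between
territories (no inhibition beyond the merge rule), midden turnover
between years, GPS positioning error, detection failure, and any
vegetation–terrain coupling beyond smoothness. Passing tests therefore
demonstrate that the pipeline recovers signals of the stated shape from
data of the stated geometry and noise level — not that it would rank
predictors correctly under survey biases absent from the generator.

## Parameter-recovery experiment

The recovery experiment (`middensdm.experiments`) draws labels with only
the canopy-height and trail-distance responses active, on a scaled-down
160 × 130 m landscape (~2 280 cells) whose smoothing bandwidths are scaled
proportionally so the field keeps a comparable number of independent
habitat patches. The model is fit on the full ten-layer derived stack, so
eight inactive layers compete. Success criteria: the two active
predictors take the top two importance ranks (in ≥ 2 of 3 seeded runs),
and the canopy-height partial dependence changes sign within 9 ± 2 m of
the generative breakpoint, probed on a grid spanning the response ramp
(4–14 m, symmetric about 9 m so centering does not move the crossing).

The recovery fit uses interaction depth 4 rather than the pipeline's
depth-10 default. Exact deep trees memorize Bernoulli label noise through
continuous nuisance layers (slope, aspect and elevation offer near-unique
split thresholds), which inflates their summed-improvement importance
above weak, non-monotone true signals without changing the fitted
response shape; a shallower ensemble measures the signal ranking rather
than this memorization floor. This is a property of summed-improvement
importance for deep exact trees generally, and is the reason importance
tables from such models should be read with the ensemble depth in mind.

## Numerical choices

* Nearest-rank quantile for the occupancy threshold uses an ε-guarded
  ceiling (`⌈(1−c)·N − 10⁻⁹⌉`) against floating-point error in (1−c)·N.
* Newton leaf steps return 0 when the denominator Σ wp(1−p) < 10⁻¹²
  (saturated leaves).
* IDW treats distances < 10⁻⁹ as exact hits.
* Reported densities use decimal half-up rounding (never banker's
  rounding), at 2 dp except the occupied-area midden density at 1 dp;
  full-precision values are always retained in the JSON outputs.
* All random streams derive from `numpy.random.default_rng` seeded with
  explicit (seed, stream) pairs, so stages are independently reproducible.

## Problem sizes

The test suite exercises the full pipeline at reference scale
(879 × 849 m, ~83 000 cells, ~1.4 M returns, 400 trees; about 35 s per
run on one CPU) for the reproducibility check, and scaled-down landscapes
(100 × 100 cells and below) elsewhere; oracle-equivalence checks run on
≤ 30 × 30 grids where O(n²) brute force is exact and fast. These sizes
were chosen so a complete run of suite plus acceptance script stays in
the low minutes while still covering the reference geometry once.

## Known limitations

* Aspect's 0/360 wrap is not encoded circularly.
* The RIO is training-set-internal; no cross-validation or spatial
  block validation is implemented.
* The occupancy threshold is an empirical quantile with no uncertainty
  attached.
* Rasterize-then-EDT distances differ from exact vector distances by up
  to one cell diagonal.
* The midden–squirrel conversion is an assumption-driven bracket; the
  generator provides no ground truth for it.
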