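# Methods

This note documents the models, the synthetic reef-scape, the numerical
choices, and the known limits of `reefniche`.

## Scope and data model

The pipeline maps, per coral species, the probability of occurrence across
a reef tract from presence/absence survey sites and eight gridded
environmental predictors: bathymetry (m), mean / variance / range of daily
SST (°C), mean chlorophyll-a (mg m⁻³), mean K490 turbidity (m⁻¹), mean
daily wave energy (kJ m⁻²), and distance from coast (km). All spatial data
travel as `RasterGrid`: a north-up, row-major grid on a projected planar
kilometre coordinate system with the origin at the top-left corner
(x east, y south), nodata −9999, cell (row, col) = (⌊y/cs⌋, ⌊x/cs⌋) with
half-open cell intervals. Working in planar km avoids geodesic complexity
at tract scale; real-mode inputs are expected already projected. Rasters
persist as plain-text ESRI ASCII grids and polygons as GeoJSON — the
simplest interoperable formats that need no compiled GIS stack.

## Predictor derivation

* **Daily aggregation.** Mean, variance and range are computed per pixel
  over the daily stacks, ignoring per-day nodata; a pixel is nodata only if
  every day is missing. Variance is the *population* variance (divide by
  n); the flavour is recorded in layer metadata so it is auditable.
* **Distance from coast** uses the exact Euclidean distance transform, so
  each sea cell holds the exact center-to-center distance to the nearest
  land cell (verified against a brute-force oracle in the tests).
* **Harmonization** resamples every layer to the target 1-km grid
  (bilinear for continuous layers, nearest for masks; any target cell whose
  source neighbourhood touches nodata becomes nodata) and masks to a 1-km
  buffer of the reef polygons. The operation is idempotent.
* **Predictor exclusion.** Pearson correlations over complete-case sites;
  from each pair with |r| ≥ 0.70 the lower-priority member of a fixed
  priority list is dropped. SST variance sits last in the list, so the
  near-collinear SST variance/range pair always resolves in favour of SST
  range. Zero-variance predictors make the correlation undefined; they are
  flagged, never silently dropped.
* **Site filtering.** Sites missing any retained predictor are removed; the
  removal report gives per-predictor missing counts and the union count
  (≤ the sum, since one site can miss several layers).

## Wave energy

Fetch — the unobstructed open-water distance looking into the wind — is
computed per sea cell for 16 compass bearings (22.5° bins, bin centered on
its bearing) by exact grid ray traversal: the ray visits every cell it
crosses, and the fetch is the exact distance to the boundary where it first
enters a land cell, capped at 200 km by default (unbounded rays are
meaningless on a finite grid; the cap is recorded in metadata). A ray
passing exactly through a cell corner steps diagonally; point contact does
not obstruct. Rays that leave the grid either truncate at the edge (the
default: the boundary acts like a shore) or receive the open-water cap
(`edge_policy="open"`), which the synthetic pipeline uses because its grid
edge is a window onto open ocean, not a coastline — the truncating policy
would imprint artificial along-shore fetch gradients.

Significant wave height follows the classical deep-water forecasting
forms. With wind speed U (m s⁻¹) and fetch F (m): below a 38-km fetch the
sea is fetch-limited and H = c_H (gF/U²)^{e_H} U²/g with defaults
c_H = 0.0016, e_H = 0.5 (note H is then linear in U, so energy scales as
U²); at and beyond 38 km the sea is fully developed and H = k_H U²/g with
k_H = 0.2433. A fetch of exactly 38 km counts as fully developed. All
coefficients are config-overridable so alternative published coefficient
sets can be dropped in verbatim. Energy density is E = ρgH²/16 (J m⁻²,
reported as kJ m⁻²; ρ = 1025 kg m⁻³), averaged over the daily record.
Wind direction is meteorological ("blowing from"), and the fetch lookup
uses that upwind bearing directly. Two evaluation modes are provided —
per-day winds (default) or each cell's dominant (modal) direction with the
mean speed of that bin; ties in the modal bin resolve to the lowest
bearing. No shallow-water transformation, refraction or duration-limited
growth is modelled.

## Boosted regression trees

The estimator (`BoostedTreesClassifier`) is a from-scratch stagewise
gradient-boosting machine for the weighted Bernoulli deviance:

* **Weights.** Presences and absences are balanced to equal total weight
  (majority class 1, minority n_maj/n_min), so the intercept — the logit of
  the weighted prevalence — is 0 and the 0.5 threshold used downstream for
  suitability and confusion matrices is meaningful.
* **Trees.** Greedy best-first regression trees with at most
  `tree_complexity` splits (default 5, i.e. number-of-predictors − 2 for a
  seven-predictor model; config-exposed). Candidate splits are midpoints
  between adjacent distinct sorted values; the split maximizing the
  weighted squared-error reduction of the gradient residuals y − p wins,
  with ties broken deterministically (first feature in input order, then
  lowest threshold). Terminal values are one Newton step
  Σwr / Σw·p(1−p) over the node's bagged cases; a degenerate denominator
  yields a zero increment. `min_obs_node` (default 5) bounds leaf sizes.
* **Bagging.** Each tree is fit on ⌈0.8 n⌉ training cases drawn without
  replacement (gbm-style bag fraction); a `bag_with_replacement` switch
  gives true bootstrap bags.
* **Tree-count selection.** With `cv_folds ≥ 2` (default 5), each inner
  fold of the training split fits the boosting sequence to `max_trees`
  while recording held-out deviance after every tree; the selected size is
  the argmin of the mean held-out deviance at or beyond `initial_trees`
  (default 30), and the final model is refit on the full training split at
  that size. If the argmin sits at the cap the model is flagged
  unconverged. `cv_folds < 2` skips selection and uses `max_trees`
  directly — useful for property tests and simulation studies.
* **Interpretation.** Relative influence accumulates each split's gain to
  its predictor and normalizes to 100 % (uniform with a warning if no split
  gained anything). Partial dependence clamps one predictor across a value
  grid, averages the link over the reference rows, and reports the inverse
  link (or the raw link on request).
* **Determinism.** All randomness (fold assignment, bagging) flows from a
  single seeded generator; identical configuration reproduces identical
  models.

The default learning rate 0.0015 matches common niche-modelling practice
for ~1000-site surveys and implies sequences of thousands of trees. The
bundled demo and the simulation studies use a learning rate of 0.05–0.1
with a few hundred trees — the package's own choice of scale for
illustration and testing; the statistical behaviour being verified
(oracle-equality of splits, deviance monotonicity, influence normalization,
driver recovery) does not depend on the shrinkage.

## Evaluation

Sites are split into five near-equal seeded folds; models train on four
(80 %) and are scored on the fifth. Diagnostics are the Mann–Whitney AUC
(ties counted ½, hence invariant under monotone transforms of the scores)
and the 2×2 confusion matrix at threshold 0.5, where scores equal to the
threshold classify positive. AUC is reported on the held-out fold only and
labelled as such.

## Suitability, areas and patches

Fitted models are projected onto the harmonized stack (a cell predicts
only if every predictor is valid there). Habitat is suitable where
p > 0.5 strictly ("above" the 50 % value; exact ties are excluded). Areas
are cell counts × cell area (cell size², planar). Subregion labels
partition the reef band into contiguous blocks; buffer cells just outside
the band inherit the nearest label so every modelled cell is accounted
for. Species enter modelling only if site prevalence ≥ 10 % (rare-species
models are unstable), with an explicit exception list and the exclusion of
single-class species. In the report tables, species rows are ranked by
total suitable area; the per-subregion mean is computed over the modelled
species only (excluding the extent row), and subregion rank ties break to
the lower column index.

The disturbance simulation thresholds the probability surface at an
increasing series (default 0.50–0.90 in steps of 0.05; the series is
configurable), labels the surviving habitat patches as connected
components (8-connectivity by default — diagonal reef cells form one patch
at 1-km resolution; 4-connectivity available), and measures each patch's
Euclidean nearest-neighbor distance: the minimum center-to-center distance
between a cell of the patch and a cell of any other patch (edge-to-edge in
the raster sense, as in standard landscape-metrics practice; the centroid
variant is deliberately not used). The mean ENN over patches indexes
fragmentation; with fewer than two patches it is undefined and the sweep
row is flagged — the signature of metapopulation collapse.

## The synthetic reef-scape

The generator emulates the statistical shape of a reef-tract survey, not
any real geography:

* a contiguous coastline on the western grid edge whose width wiggles as
  stationary smoothed noise (a random-walk coast would imprint spurious
  along-shore trends in fetch);
* a coast-parallel reef band between 4 and 10 km offshore, partitioned
  into contiguous subregion blocks (10 by default);
* bathymetry deepening with distance from coast plus a smooth independent
  relief field;
* daily SST = latitudinal base gradient + seasonal sinusoid whose
  amplitude varies across the tract as a smooth field (so per-pixel SST
  range varies cell to cell); the seasonal cycle spans the record when it
  is shorter than a year, so short test records still see the full range;
* chlorophyll-a and K490 decaying offshore, modulated by independent
  smooth water-quality fields and daily lognormal flutter;
* daily spatially-uniform wind (gamma speeds, von Mises directions around
  an easterly prevailing bearing) modulated by a persistent spatial
  exposure field.

The smooth-field structure is calibrated so that, at the sites, only the
SST variance/range pair is near-collinear (r ≈ 0.99) while every other
predictor pair stays moderate — the configuration a real survey of this
kind exhibits, in which exactly seven of the eight candidate predictors
survive the r ≥ 0.70 exclusion. Sampling noise can still push a borderline
pair past the threshold on occasional seeds; the pipeline handles any
retained set.

Virtual species are defined by additive logit responses — linear terms,
Gaussian bumps (optimum, width, height) and step terms — over the true
predictor values at uniformly sampled reef-band sites. The intercept is
calibrated by bisection so the mean occurrence probability equals the
target prevalence (the mean is strictly increasing in the intercept, so
the root is unique); realized prevalence converges to the target as site
count grows (±2 points at n = 5000 in the tests). Missing values are then
injected into the *recorded* predictor columns at configured per-predictor
rates, leaving the presence draws untouched. Sites are treated as unique
(no revisit structure).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: species co-occurrence and residual spatial
autocorrelation, imperfect detection (false absences from 10 m² transects
inside 1 km² cells), observer effects, temporal non-stationarity across
survey years, and real coastline/bathymetry geometry. Tests on the
synthetic reef-scape validate the *machinery* (that known responses are
recovered, that accounting is exact); they are not evidence about any real
reef tract.

## Numerical choices and degenerate inputs

* Gains, Newton steps and deviances guard against zero denominators
  (ε = 10⁻¹²); probabilities are clipped away from 0/1 in the deviance.
* Constant features yield no candidate splits; a fully constant gradient
  yields a single-terminal zero tree.
* Degenerate masks (all land / all sea), empty stacks, empty grids, and
  single-class labels raise typed errors rather than returning silently
  wrong numbers.
* The pipeline fans a single global seed out to per-stage child seeds by
  fixed offsets, so stages can be rerun independently yet reproducibly;
  the run manifest records the config hash and every output file.

## Problem sizes

The bundled demo uses a 50 × 80 km grid, 90 daily fields, 400 sites and
three virtual species; the simulation studies use n = 1000 sites, seven
predictors and 20 seeds; brute-force oracle comparisons run on grids up to
100 × 100. These are the package's chosen scales for fast, deterministic
validation; everything accepts larger inputs through the same interfaces.
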