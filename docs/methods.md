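# Methods

This note documents the models, algorithms and design choices behind
`scalesdm`, in the spirit of the model documentation shipped with packages
like statsmodels or msprime: what is computed, under which assumptions, with
which defaults, and what the synthetic experiments do and do not establish.

## 1. The presence-background model

### Objective

Presence-only data are modeled as a Gibbs distribution over landscape
cells, the maximum-entropy formulation that is equivalent to an
inhomogeneous Poisson point process (IPP) thinned to a background sample.
With presence feature rows f(x₁)…f(x_n) and a background sample B, the
coefficient vector β maximizes

    L(β) = Σ_i β·f(xᵢ) − n_p · log Σ_{z∈B} exp(β·f(z)) − λ‖β‖₁.

The penalty λ applies to this summed log-likelihood directly. The default
λ = 0.05·√(ln n_p) grows very slowly with the number of presences; on the
standardized feature scale it removes coefficients with essentially no
support while leaving moderate effects almost unshrunk. This default keeps
the estimator close to maximum likelihood, which in turn keeps AICc
comparisons (Section 4) meaningful: K is the count of nonzero coefficients,
and a near-ML fit is the regime where the AIC machinery is theoretically
grounded.

### Features and standardization

Predictors are standardized to zero mean and unit variance over the pooled
training rows (presence + background); the constants are frozen in the
fitted object, which makes raw predictions invariant to affine rescaling of
any input variable. The default feature classes are linear and quadratic.
Pairwise products and one-sided hinge features (knots at pooled-sample
quantiles, 8 per variable) are available but off by default: with tens to
a few hundred presence cells per design cell — the regime of the smaller
extents — the quadratic expansion is as much flexibility as the data
support. Predictors constant over both presence and background are dropped
with a warning, and expanded feature columns that add no rank (duplicates,
exact collinearity) are pruned by a greedy Gram–Schmidt pass with tolerance
1e−6 on the residual norm.

### Optimization

The L1 term is handled exactly by the split β = β⁺ − β⁻ with β± ≥ 0, which
converts the non-smooth problem into a smooth bound-constrained one solved
by L-BFGS-B (analytic gradient, ftol 1e−8, at most 500 iterations).
Coefficients below 1e−10 in magnitude are snapped to zero. The fit is
deterministic given its inputs; the only randomness anywhere in the
pipeline enters through explicit seeds. The test suite verifies the
optimizer against an independent derivative-free (Powell) maximization of
the identical objective on small discrete landscapes, with agreement better
than 1e−4 in every cell probability.

### Output scales

* `raw`: exp(β·f(x)) normalized to sum to 1 over the *training* background —
  the Gibbs probability.
* `cloglog`: 1 − exp(−e^H · raw), where H is the entropy of the fitted raw
  distribution over the training background; a bounded (0, 1) suitability
  scale suitable for mapping. All evaluation metrics are rank-based or
  threshold-swept, so the choice of output scale does not affect AUC and
  affects the max-TSS *threshold* value only, never the max TSS itself.
  Values outside the training range are evaluated as-is (no clamping).

### Diagnostics

* **Permutation importance**: each predictor's values (all of its expanded
  features together) are permuted across the pooled training rows; the drop
  in training AUC, floored at zero, is normalized across predictors to sum
  to 100. A full column permutation is used — the standard implementation
  of "slightly changing the values" of a variable.
* **Response curves**: cloglog prediction along an even grid spanning the
  variable's observed training range, other variables held at training
  means.
* **AICc**: LL is the sum of log raw probabilities of the presences
  normalized over a supplied background (training background by default),
  K the number of nonzero coefficients, AICc = 2K − 2LL + 2K(K+1)/(n−K−1).
  When n ≤ K + 1 the correction is undefined and NaN is returned; fold
  averages skip NaN folds and design cells where no fold is computable
  report NaN. AICc is only ever compared between variable sets at the same
  extent and grain — changing either changes the sample and makes the
  criterion incomparable.

## 2. Evaluation metrics

AUC is computed in Mann–Whitney rank form with mid-rank tie handling.
The maximum TSS sweeps every unique predicted value t, with
sensitivity = fraction of presence predictions ≥ t and specificity =
fraction of background predictions < t; the smallest maximizing threshold
is returned, making results deterministic under ties. The "correlation
coefficient" is the Pearson correlation between pooled test predictions
and the 0/1 presence label (point-biserial). Fold results are averaged
metric-wise; thresholds are averaged, never re-optimized on pooled folds.
The same background sample is reused across the five folds (only presences
are partitioned).

## 3. Study design

* **Level 1**: the domain is tiled by square 50 km² blocks anchored at the
  top-left corner; blocks with ≥ 20 presence points qualify as replicates.
* **Level 2**: qualifying blocks are drawn in seeded random order and
  buffered to concentric 500 km² squares (clipped to the domain); a buffer
  is accepted only if it overlaps no previously accepted one, until 9 are
  accepted or candidates are exhausted. Squares rather than an unspecified
  buffer shape keep area bookkeeping exact.
* **Level 3**: in synthetic mode, the truth regions of the generator (the
  stand-ins for mountain ranges); **level 4** is the full landscape.
* **Background**: cell centers of non-nodata cells inside the extent below
  3600 m elevation (the alpine no-bamboo ceiling for the motivating
  system), sampled uniformly without replacement up to n = 10,000; if fewer
  are eligible, all are used — the small-extent/large-grain corner where
  only a dozen cells exist is deliberately retained, because that is where
  accuracy degradation originates. Presence cells are not excluded from the
  background pool (the MaxEnt background convention).
* **Folds**: a true 5-fold partition of presence cells (each cell tests
  exactly once), the stricter reading of "five random 80/20 combinations";
  an `independent_splits` option provides the looser reading.

## 4. The factorial experiment

For every extent replicate × admissible grain × variable set, the driver
crops the predictor ladder, rasterizes presences at that grain, samples
background, splits folds, fits, evaluates and records. Grain availability
follows the data-availability structure of multi-source predictor suites:
the base set (elevation, slope, percent forest, distance to road, distance
to stream) exists at all seven grains 30…1920 m; the 11-band phenology set
enters at 240 m (after PCA reduction to at most 5 components explaining
≥ 99% of variance, computed once at 240 m, components then aggregated
upward); the five climate bands enter at 960 m. Aggregation is successive
factor-2 block means (a median variant is available); blocks that are
entirely nodata become nodata, partial trailing blocks are dropped.

Design cells that cannot be modeled (fewer presence cells than folds, no
eligible background) are recorded as skipped rows, not dropped: records +
skips always equal the full factorial size. A master seed derives every
child seed by hashing the design-cell labels (replicate, grain, variable
set, fold), so results are byte-reproducible and adding design cells never
perturbs existing ones.

Replicate summaries report mean and sample SD over replicates of the
fold-averaged metrics; scale contrasts are reported as replicate-level
intervals rather than formal hypothesis tests. Parsimony comparisons count
the fraction of replicates whose AICc rose by more than 2 (reduced
parsimony), fell by more than 2 (improved), or changed by at most 2, for
base vs base+phenology at 240 m and base(+phenology) vs +climate at 960 m.

Cross-extent transfer fixes a level-1 target, holds out 20% of its presence
cells and its background sample once, and evaluates the models trained at
the target itself and at every nesting extent on exactly that test set, at
the 30 m grain with base variables.

## 5. The synthetic landscape generator

The generator emulates the *structure* of a range-wide habitat study, not
any particular geography:

* **Fields**: zero-mean Gaussian random fields with exponential
  autocovariance, synthesized by circulant embedding on a doubled torus
  (exact marginal variance, tiny negative embedding eigenvalues clipped).
  Range 0 degenerates to i.i.d. noise.
* **Predictors**: elevation = 2600 + 700·field + a 300 m west–east trend
  (mountainous scale, a meaningful fraction above the 3600 m ceiling);
  slope derived by Horn's method; percent forest = 100·logistic(field),
  clipped to [0, 100]; roads and streams are random domain-spanning
  polylines turned into Euclidean distance rasters; 11 phenology bands are
  mixtures of 3 latent fields with small noise so many band pairs correlate
  above 0.9 (the motivation for PCA reduction); 5 climate bands are
  generated at 960 m and bilinearly resampled down, mimicking coarse
  climate products.
* **Truth**: suitability = expit(intercept_r + Σ a_{r,v} z_v + b_{r,v} z_v²)
  with per-region coefficients on standardized predictors; one region means
  stationary truth; the default partition is quadrants (or vertical strips
  for non-square counts).
* **Survey**: the domain is tiled by square survey cells (default 1414 m ≈
  2 km²); detections per surveyed cell are Poisson with mean
  detection_scale × mean suitability in the cell, placed uniformly within
  it — a line-transect-style design in which the *cell*, not the exact
  point, carries the sampling intensity. The default detection_scale = 12
  yields tens of presence points per qualifying 50 km² block and hundreds
  to ~a thousand per 30 × 30 km landscape, matching the order of magnitude
  of range-wide sign surveys.

What the generator does **not** emulate: realistic topography (drainage,
orography), bamboo dynamics, spatially biased survey effort, observer
error, or irregular mountain-range polygons (regions are rectangular
blocks). Passing tests therefore demonstrate that the pipeline recovers
known truth and reproduces the qualitative scale phenomena *under these
idealized conditions*; they do not certify accuracy values on real survey
data.

## 6. Canned scenario experiments and problem sizes

The `scenarios` module fixes the study conditions used by the test suite
and the reproduction script; sizes were chosen to exercise each phenomenon
clearly at desk scale:

* **Recovery** (20 seeds): 250×250-cell stationary landscapes, a rare
  specialist truth (intercept −3.5, |linear| = 1.5 on elevation, forest and
  distance-to-road) surveyed with fine 300 m cells (several hundred
  presences). Rarity matters: presence-background AUC is bounded well below
  1 for a common species no matter how good the fit, so the rare-specialist
  setting is where a held-out AUC target near 0.8 is a meaningful test of
  the estimator rather than of prevalence.
* **Grain effect** (default 1000×1000 landscape, ≈14 level-1 replicates):
  base models at 30 m and 1920 m, five folds; the coarse grain collapses
  ~30 presence cells to ~8 and the background to a handful of cells,
  reproducing the fine-grain advantage in the smallest extent.
* **Nonstationarity** (20 seeds): 240×240 landscapes, four regions, two
  with sign-flipped elevation/forest responses; region models vs one global
  model on identical within-region test sets.
* **Parsimony** (20 replicates): 150 presences against 10,000 background
  (level-2-like sizes), 2-variable truth plus 5 pure-noise predictors.
* **Monotonicity** (6 block replicates on a 512×512 landscape): presence
  cells counted along the full 30→1920 m ladder.

## 7. Numerical conventions and edge cases

* Grid convention: top-left origin, row 0 northmost, y decreasing with row
  index, half-open cells [edge, edge+cell); points map to cells by floor
  division. This removes all 0/1-based and boundary ambiguity.
* Nodata: excluded from every statistic; all-nodata aggregation blocks
  become nodata; bilinear resampling fills nodata by nearest valid neighbor
  for interpolation but marks output cells whose own center is nodata.
* Slope: Horn's 3×3 stencil in degrees with edge replication at borders —
  the common GIS default.
* Distance rasters are computed at the native 30 m grain and aggregated up
  the ladder with the other base variables, consistent with deriving all
  variables once and coarsening the set.
* PCA on the phenology bands is correlation-matrix PCA (bands are centered
  and scaled) because multi-band products mix units; components are capped
  at 5 by default.
* Ties in ranks use mid-ranks everywhere; max-TSS returns the smallest
  maximizing threshold.
* ESRI ASCII grids are written with exact integer formatting where values
  are integral and `repr` floats otherwise, so a write–read round trip is
  bit-faithful.

## 8. Known limitations

* Extents are axis-aligned rectangles; irregular polygon extents (true
  mountain-range boundaries) are out of scope.
* The threshold/category feature classes of full MaxEnt, clamping, and
  sample-bias grids are not implemented.
* Exact numeric replication of any particular MaxEnt build is not
  attempted (feature classes, regularization multipliers and version
  details differ between builds); the implementation targets the documented
  objective, not a binary.
* All coordinates are planar meters; no projections or geodesic areas.
* The factorial driver is single-process; desk-scale problem sizes run in
  minutes, range-wide real-data factorials would need external
  parallelization.
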