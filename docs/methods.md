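# Methods

This note documents the models and procedures implemented in `traitscape`,
the assumptions behind them, the defaults and why they were chosen, and
what the synthetic-world experiments do and do not demonstrate.

## 1. Trait assignment and community statistics

Species strings are normalised to their first two whitespace-delimited
tokens, lowercased.  This deliberately blunt rule strips authorities,
infraspecific epithets and hybrid markers; single-token names cannot form a
binomial and are treated as unmatched rather than guessed.  Species trait
means are arithmetic means over all measurements sharing a normalised
binomial; intraspecific variation is ignored by construction.

Plot community-weighted means use the cover-normalised convention
`CWM = Σ cover·t̄ / Σ cover` over trait-matched species.  Unmatched species
are removed and the remaining cover weights renormalised (a
`renormalize=False` switch keeps raw covers as weights so both conventions
can be compared); plots with zero matched cover are dropped.  The
renormalised convention is the standard one in the CWM literature and makes
the statistic invariant to rescaling all covers in a plot.  Every matching
step returns a retention report (records and species in/out) because the
coverage gap of trait databases is the dominant loss channel in this
workflow.

Occurrence records are "tagged" with their species mean; the per-cell
arithmetic mean of tagged records is the frequency-weighted mean (FWM).
Under equal detectability and spatially uniform effort within a cell, the
FWM is a Monte-Carlo estimate of the cell's abundance-weighted CWM; the
test suite verifies the mean absolute deviation shrinks as per-cell depth
grows (20 → 100 → 500 records).

## 2. Gridding

All coordinates live on an abstract equal-area plane in km, so cell area is
exact by construction and no geodesy is needed.  Cells are half-open
squares under a floor rule (a boundary point belongs to the higher-index
cell), giving a partition without double counting.  The default resolution
ladder is cell edges of 1, 22, 55, 111 and 222 km; each resolution gets
independently built grids and models rather than upscaled maps.  Because
these edges are mutually indivisible, coarsening drops the ragged trailing
edge of the finest grid instead of demanding exact tiling.

Occurrence density control: cells with fewer than 10 tagged records are
dropped (too few for a stable FWM), cells with more than 500 are thinned to
exactly 500 by uniform sampling without replacement, independently at each
resolution.  The rule is applied after trait matching, so the thresholds
count usable records; a config switch is not provided for pre-matching
order because the tagged table is the only one the gridder sees.

Predictor aggregation to coarser grids is an area-weighted mean ignoring
missing cells.  With square cells on a shared origin the overlap weights
are uniform, so the operation reduces exactly to a NaN-aware block mean;
the valid-area-weighted global mean is conserved for complete layers.
Upsampling is unsupported.

Labels are Yeo–Johnson transformed before training.  λ is fitted by
maximum likelihood per trait on the survey plot-CWM distribution and reused
everywhere — for every subset, resolution, and for any external values
brought onto the label scale — so observed and predicted values are always
compared on a single scale.  The forward/inverse pair round-trips to 1e-8;
λ is stored in run metadata and raster sidecars.  Training rows keep
missing predictor values as NaN but rows with fewer than 60 % of predictors
present are excluded (boundary kept at exactly 60 %).

## 3. Spatial block cross-validation

Random K-fold CV is optimistic for spatial data: validation points closer
to training points than the label's autocorrelation range are
near-duplicates.  The blocking procedure:

1. **Range estimation.**  Matheron empirical semivariogram of the survey
   CWM values (15 bins by default, lag cap at half the maximum pair
   separation, pairs subsampled beyond 10⁶), then a pair-count-weighted
   least-squares fit of the spherical model
   `γ(h) = c₀ + c·(1.5 h/r − 0.5 (h/r)³)` for `h ≤ r`.  The range is
   bounded above by the largest observed lag: beyond it the data carry no
   curvature to identify it, and a fit at the bound (or a flat, pure-nugget
   variogram) is returned pinned to the maximum lag with a flag and a loud
   warning rather than failing — a finite hexagon width is required
   downstream.  Multiple starts guard the cubic section's local minima;
   noise-free model curves are recovered to 1e-6.
2. **Tessellation.**  Flat-top hexagons with across-flats width equal to
   the fitted range (axial coordinates, cube rounding).  Points in
   different hexagons of different folds are therefore typically separated
   near or beyond the range.
3. **Balanced assignment.**  The tessellation is fixed; 100 independent
   uniform assignments of hexagons to K = 5 folds are scored by the mean
   two-sample Kolmogorov–Smirnov p-value of the label values over all fold
   pairs (pairs with an effectively empty side score 0), and the
   best-scoring assignment wins (first occurrence on ties).  All rows —
   survey and occurrence — inherit their hexagon's fold.
4. **Splits.**  Leave-one-fold-out: training rows are everything outside
   the held-out fold (any source), validation rows are the held-out fold's
   survey CWM cells only.  Occurrence cells never validate.  Folds without
   survey rows are skipped with a warning.

The optimism-gap experiment in the test suite fits models to spatially
autocorrelated pure-noise labels (label field and predictor fields
independent): random CV reports r ≈ 0.6 where spatial CV correctly reports
r ≈ 0, paired over 20 replicates.

## 4. Models

The learner is gradient-boosted regression trees (LightGBM), which handles
missing predictor values natively by routing them to the loss-minimising
side of each split.  Defaults: 300 trees, learning rate 0.06, 31 leaves,
minimum 5 samples per leaf — sized for desk-scale tables of 10²–10⁴ rows
(the small leaf minimum matters there), single-threaded and deterministic
under the config seed.  Hyperparameters are exposed in config and fixed
before validation; spatial CV is never used to select them.

In the merged (COMB) subset, occurrence rows are weighted
`n_survey / n_occurrence` so each source contributes equal total weight;
single-source subsets get unit weights.

Optional per-split feature pruning is backward elimination on permutation
importance measured on an internal tune subsample (20 % of the split's
training rows): features whose importance is not significantly positive
are dropped and the model refitted, up to 5 rounds.  The significance
guard (default 2 null-SDs of the permutation draw, where the null SD
accounts for the intact loss being a single draw from the permutation
distribution) exists because a pure-noise feature's expected importance is
exactly zero — a hard `≤ 0` cut would drop it only half the time.  Setting
the factor to 0 restores the hard cut; an alternative `metric_gain`
criterion accepts a removal only if tune loss does not increase.  If the
pruned model ends up worse than the unpruned one beyond a 5 % relative
tolerance, the full feature set is restored.  Per-split feature sets may
differ; the final map model is trained on all rows and all features.

Permutation importance: mean increase in squared error on held-out rows
over 5 shuffles, per feature or per feature group (a group's columns are
shuffled jointly with one shared row permutation); reported values are
averaged over CV folds.  A feature the model never splits on scores
exactly zero.

## 5. Uncertainty layers

**COV** is the per-pixel sample standard deviation (denominator K−1) of
the K fold models' predictions divided by their mean, computed on the
back-transformed (original trait units) scale — transformed-scale means
can sit near zero, where the ratio is meaningless.  Pixels whose |mean| is
below 1e-6 of the global mean magnitude are masked undefined.

**DI / AOA** follows the dissimilarity-index construction: predictors are
z-scored by training mean/sd, each training row's nearest-neighbour
distance to rows in *other* folds is computed, and their mean d̄
normalises everything; a new pixel's DI is its nearest-neighbour distance
to any training row over d̄.  The applicability threshold is
`Q75 + 1.5·IQR` of the training DI (linear-interpolation quantiles,
recorded in metadata because the threshold depends on the convention); at
least 75 % of training rows are inside by construction.  Distances are
unweighted standardized Euclidean.  Missing predictor values are imputed
before any distance is computed — training-fitted per-feature medians by
default, or per-feature boosted-tree regressors (`strategy="model"`) —
so the DI surface matches the geographic extent of the predictions.

Maps are written as multi-band int16 TIFFs (prediction, COV, AOA) with
affine per-band quantization `value ≈ code·scale + offset`,
`scale = (max − min)/(2¹⁶ − 2)`, a reserved nodata code, offset-only
encoding for constant bands, and a lossless 0/1 AOA band; the JSON sidecar
stores the grid, per-band quantization, λ, seed and DI threshold.
Round-trip error is bounded by half a quantization step.

## 6. The synthetic world

The generator emulates the statistical structure the pipeline assumes,
with known ground truth:

* **Environment**: stationary Gaussian random fields from Gaussian-kernel
  smoothed white noise (wrapped boundaries).  The kernel bandwidth is
  calibrated so the package's own spherical fit recovers the requested
  range (ratio 4.45 between fitted range and kernel σ; realized ranges
  scatter roughly ±25 % around the request).  An extra field is
  quantile-sliced into contiguous strata standing in for biome categories.
* **Species**: unique two-word binomials; independent Gaussian niches per
  environment axis (uniform optima, log-uniform breadths); traits drawn
  from configurable distributions, optionally linked linearly to a niche
  optimum — the switch that plants a learnable trait–environment signal.
* **Communities**: per-cell covers proportional to the product of niche
  responses, renormalised; responses below an absence floor (1e-4) are
  absences, and cells where everything is absent are empty.
* **Surveys**: a Thomas-like clustered point process; each plot records
  its cell's complete relative covers (so plot CWMs are exact functionals
  of the latent field), optionally truncated to the top-k species.
* **Occurrences**: cells drawn proportional to an effort surface, species
  within a cell proportional to cover × detectability, location uniform in
  the cell.
* **Trait database**: an exact `round(coverage_fraction · n)` subset of
  species receives multiplicative-noise measurements (coefficient of
  variation `intraspecific_cv`), a fraction of emitted names carrying
  authority suffixes.

Default world (the `WorldConfig` defaults): a 444 km square at 1 km
resolution, environment range 60 km, 5 predictor layers of which 3 drive
niches, 36 species, 600 plots in 8 clusters (25 km dispersion), 50 000
occurrences with effort skewed by the first environment layer, 70 % trait
coverage with CV 0.15 and 4 measurements per species, two traits.  These
sizes keep the full resolution ladder exercisable in a couple of minutes
on one CPU while preserving the qualitative regime of the real workflow:
occurrence cells outnumber survey cells several-fold, the trait database
is incomplete, and the two coarsest resolutions are data-starved (their
tasks are skipped with warnings, as they would be on any small extent).

What the generator does **not** emulate: temporal dynamics and phenology,
dispersal and species interactions, realistic taxonomy beyond authority
suffixes, detection error in surveys, structured (e.g. road-biased)
occurrence effort beyond a smooth effort surface, and real predictor
collinearity structure.  Passing tests therefore demonstrate correctness
of the machinery and recoverability under the stated assumptions, not
performance on real survey/occurrence/trait data.

## 7. Numerical choices and degenerate inputs

* Ties in cell assignment go to the higher-index cell (half-open cells).
* `fit_spherical` needs ≥ 3 bins; constant values give a zero variogram
  (flagged); coincident points are a degenerate-geometry error.
* Degenerate (zero-variance) label distributions get an identity
  transform (λ = 1) rather than an ML fit.
* KS balancing uses `scipy.stats.ks_2samp(method="auto")`.
* `nRMSE` normalises by the observed range of the pooled validation set by
  default (mean and IQR normalisations selectable and recorded); a zero
  range flags nRMSE as undefined instead of raising.
* R² = 1 − SSE/SST on pooled pairs is reported alongside r and nRMSE,
  never alone.
* The pipeline refuses to write into a non-empty output directory unless
  overwriting is requested, and every output directory contains the
  resolved config and seed.

## 8. Known limitations

* The hexagon-fold procedure assumes a single isotropic range per trait;
  anisotropy and nonstationarity are out of scope.
* Range estimates at or beyond the largest observable lag are pinned and
  flagged; blocking then uses the largest observable scale, which may
  under-separate folds on domains much smaller than the true range.
* The AOA construction inherits the limitations of nearest-neighbour
  distances in standardized predictor space: it is blind to directions the
  model ignores unless importance weighting is added.
* Model-based imputation and importance-weighted DI are provided as
  options but the defaults (median imputation, unweighted distances) are
  deliberately the simplest defensible choices.
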