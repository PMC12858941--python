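# traitscape

Community trait mapping from vegetation surveys and opportunistic species
occurrences, with spatially honest validation and applicability-aware
uncertainty layers.

## The problem

Plant functional traits (leaf area, plant height, leaf nitrogen, ...) vary
across the globe with climate, soil and vegetation structure.  Wall-to-wall
trait maps are built by (1) assigning database trait values to species
records, (2) aggregating those values into gridded community statistics, and
(3) training models that predict the gridded statistic from environmental
predictor layers.  Two record sources with complementary strengths feed this
workflow:

* **vegetation surveys** (plots with per-species relative cover) yield the
  community-weighted mean, `CWM = Σ_s cover_s · t̄_s / Σ_s cover_s`, where
  `t̄_s` is the species mean trait — precise but sparse and clustered;
* **opportunistic occurrences** (point records of single species) yield the
  frequency-weighted mean, `FWM = (1/n) Σ_records t̄_s(record)` per grid
  cell — noisy and biased, but vastly more abundant and broader in coverage.

`traitscape` implements this pipeline end to end, including the parts that
make its validation honest:

* name matching by two-word binomial truncation, species-mean assignment,
  plot CWMs and trait-tagged occurrences with retention bookkeeping;
* equal-area gridding at multiple resolutions with a 10–500 records-per-cell
  density control for occurrences, and survey-precedence merging of the two
  sources (the SCI / CIT / COMB data subsets);
* Yeo–Johnson label transforms, ≥60 % predictor-completeness filtering, and
  missing-value-tolerant gradient-boosted regression trees (LightGBM) with
  inverse-proportion source weighting;
* spatial block cross-validation: a spherical semivariogram estimates the
  CWM autocorrelation range, the domain is tessellated into range-sized
  hexagons, and hexagons are assigned to 5 folds by the best of 100 random
  assignments under a mean Kolmogorov–Smirnov balance score; validation rows
  are survey CWMs only;
* per-pixel uncertainty: the coefficient of variation (COV) of the fold
  models' predictions, and the dissimilarity index (DI) / area of
  applicability (AOA), where a pixel is applicable when its standardized
  predictor-space nearest-neighbour distance satisfies
  `DI ≤ Q75 + 1.5·IQR` of the training DI distribution;
* quantized int16 multi-band raster bundles (prediction, COV, AOA) with JSON
  sidecars.

Because the datasets this method is normally applied to are restricted and
enormous, the package ships a **synthetic world generator** with fully known
ground truth — autocorrelated environment layers, Gaussian niche-driven
communities, clustered survey plots, effort-biased occurrences, and an
incomplete noisy trait database — so every stage is testable at desk scale.

## Worked example

```python
from traitscape import WorldConfig, simulate_world, ModelConfig
from traitscape import gridding, matching
from traitscape.model import TraitMappingModel

world = simulate_world(WorldConfig(extent_km=132, n_plots=600,
                                   n_occurrences=30000, env_range_km=35,
                                   traits=("leaf_area",)), seed=7)
means = matching.species_means(world.trait_db)
cwm, report = matching.plot_cwm(world.surveys, means, "leaf_area")
params = gridding.fit_transform(cwm["cwm"].to_numpy(), trait="leaf_area")
grid = gridding.grid_trait_values(cwm, world.grid, "cwm_mean")
model = TraitMappingModel.from_grids(grid, world.env, params,
                                     ModelConfig(trait="leaf_area",
                                                 subset="SCI", seed=7))
res = model.fit()
print(res.summary())
```

prints

```
Trait mapping results
==========================================================
trait:              leaf_area
resolution:         1 km
data subset:        SCI
training rows:      585
CV folds used:      5
hexagons / range:   29 @ 28.68 km
fold balance (KS p): 0.2304
----------------------------------------------------------
pooled Pearson r:    0.9902   (n = 585)
nRMSE (range):       0.0297
R^2:                 0.9799
----------------------------------------------------------
top features (mean permutation importance):
  env_0                 0.04677
  env_1                 0.00107
  ...
```

The pooled Pearson r (0.99 here) is computed on the survey CWM rows of each
held-out spatial fold, pooled over folds — the folds are hexagons sized to
the fitted 28.7 km autocorrelation range, so validation plots are spatially
independent of training plots.  nRMSE is the RMSE divided by the observed
range of the validation CWMs.  `env_0` dominates the permutation importances
because the generated trait is linked to that niche axis.  Uncertainty
layers follow from the same results object:

```python
up = res.uncertainty(world.env)
print(f"AOA coverage: {up.percent_inside:.1f}%  DI threshold: {up.di_threshold:.3f}")
# AOA coverage: 98.8%  DI threshold: 2.007
```

The full pipeline (simulate → match → grid → folds → fit → map → score,
for every trait × resolution × subset task) runs from a YAML config:

```bash
traitscape run out/ --seed 1            # or: traitscape run out/ --config my.yaml
traitscape simulate world/ --seed 3     # just write the synthetic input tables
traitscape plan --config my.yaml        # enumerate the model tasks
```

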