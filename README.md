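# drycover

Multi-resolution mapping of forest cover in drylands: fine-resolution
land-cover classification from spectral-temporal compositing metrics,
upscaled to coarse-resolution *sub-pixel* forest-cover fractions by random
forest regression, with stratified accuracy assessment and multi-scale map
comparison. A seeded synthetic-scene generator provides landscapes with
known class labels and known fractions, so the entire chain runs — and is
tested — as a parameter-recovery experiment on a desk.

**Who it is for.** Remote-sensing and landscape-ecology researchers who
work with sparse, phenologically diverse tree cover, where a mid-summer
snapshot confuses deciduous forest with herbaceous vegetation and coarse
pixels are almost never pure.

## The method

1. **Compositing** (30 m, Landsat-like). From a multi-year stack of 6-band
   reflectance with cloud/snow/gap masks, build three predictor sets: a
   single-date composite (clear observation closest to DOY 210), and
   spectral-temporal metrics — per band the mean, median, sd, 25th and 75th
   percentile of all clear observations — over one year or a three-year
   epoch.
2. **Classification.** A random forest (1000 trees, node size 10,
   mtry = ⌊√p⌋) maps predictors to a 7-class legend (deciduous / evergreen /
   mixed forest, wetland, herbaceous, barren, water; forest ≡ tree cover
   > 30%). Accuracy: disproportionate stratified sample (300 pixels per
   mapped class) → error matrix → overall accuracy, commission, omission.
3. **Coarse-series preparation** (240 m, MODIS-like). Merge Terra- and
   Aqua-style 16-day composites into an 8-day series by compositing DOY,
   screen reliability flags, remove residual outliers via STL remainders
   (|remainder| > 3 robust sd), smooth with a Savitzky–Golay filter, and
   reduce to 90 seasonal statistics (6 signals × 3 seasons × 5 statistics).
4. **Fraction regression.** Per-coarse-pixel reference fractions come from
   the fine land-cover map; training locations respect a 1000-m minimum
   distance; one regression forest per forest type predicts fractions,
   and overall forest cover is the clipped sum. Validation on strata
   (predicted cover > 0 vs = 0) reports Pearson's *r* and

   NRMSE = √( Σᵢ (Pᵢ − Rᵢ)² / n ) / R̄

5. **Map comparison.** Tree-cover products are harmonized (loss → 0%,
   gain → 100%, strict 30% forest threshold), block-mean aggregated
   (e.g. native → 4× → 20×), and compared by Pearson's *r* and OLS slope
   over the union of nonzero-cover pixels, plus per-zone cover statistics.

See `docs/methods.md` for assumptions, numerical conventions, and what the
synthetic generator does and does not emulate.

## Worked example

One synthetic replicate (256 × 256 fine grid, 8× coarse factor, three years
of acquisitions) through the full chain:

```python
from drycover.study import StudyConfig, run_replicate

cfg = StudyConfig(n_rows=256, n_cols=256, n_train_per_class=200,
                  n_fraction_target=600, n_per_stratum=500)
res = run_replicate(seed=7, cfg=cfg)

print("overall accuracy  single-date  :", round(res["oa_single_date"], 3))
print("overall accuracy  1-yr metrics :", round(res["oa_metrics_1yr"], 3))
print("overall accuracy  epoch metrics:", round(res["oa_metrics_epoch"], 3))
print("NRMSE overall / dec / eve / mix:",
      " / ".join(f"{res['nrmse_' + t]:.2f}"
                 for t in ("overall", "deciduous", "evergreen", "mixed")))
print("Pearson r (predicted vs true overall fraction):",
      round(res["r_overall_vs_truth"], 3))
print("forest cover: true %.2f%%, mapped %.2f%%"
      % (res["forest_percent_true"], res["forest_percent_mapped"]))
```

prints:

```
overall accuracy  single-date  : 0.677
overall accuracy  1-yr metrics : 0.962
overall accuracy  epoch metrics: 0.999
NRMSE overall / dec / eve / mix: 0.55 / 2.21 / 1.93 / 2.14
Pearson r (predicted vs true overall fraction): 0.952
forest cover: true 28.00%, mapped 29.72%
```

Reading these numbers: temporal metrics sharply outperform the single-date
composite (0.96–1.00 vs 0.68 overall accuracy) because deciduous forest and
herbaceous land are nearly identical in mid-summer reflectance but differ
in seasonal trajectory, and the three-year epoch removes the residual gaps
of the one-year series. Overall forest fraction is recovered much more
accurately (NRMSE 0.55) than any individual forest type — type-level
confusion cancels in the sum — and the predicted map tracks the true
sub-pixel fractions (r = 0.95) while reproducing the regional forest
percentage within two points.

The same workflow is available from the shell; see `drycover --help`
(`simulate`, `composite`, `classify`, `assess`, `prep-coarse`,
`train-fractions`, `predict`, `validate`, `compare`, `zonal`).

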