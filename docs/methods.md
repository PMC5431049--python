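# Methods

`drycover` implements a multi-resolution workflow for mapping fractional
forest cover in dryland regions, where forest is sparse, phenology is
diverse, and single-date optical imagery is unreliable. The workflow couples
a fine-resolution (30 m, Landsat-like) land-cover classification with a
coarse-resolution (hundreds of metres, MODIS-like) sub-pixel fraction
regression, and closes the loop with multi-scale map agreement analysis. A
first-class synthetic-scene generator provides landscapes with known class
labels and known sub-pixel fractions, so the whole chain can be tested as a
parameter-recovery experiment.

## The mapping model

**Land-cover classification.** A seven-class legend is used: deciduous,
evergreen and mixed forest (forest defined as tree cover > 30%; "mixed"
meaning neither leaf habit dominates), non-woody wetland, herbaceous land,
barren land, and water. Three predictor sets are compared:

* *single-date composite*: per band, the clear observation closest to a
  mid-summer target day (DOY 210); ties go to the earlier acquisition
  (6 predictors);
* *1-year temporal metrics*: per band, the mean, median, sample standard
  deviation, and 25th/75th percentile (linear-interpolation convention)
  over all clear observations of the focal year (30 predictors);
* *epoch temporal metrics*: the same statistics pooled over three
  consecutive years (30 predictors).

A random forest (1000 trees, terminal node size 10, mtry = ⌊√p⌋) predicts
the per-pixel class. Prediction averages per-tree class probabilities;
exact ties resolve to the lowest legend code. Accuracy is assessed by
disproportionate stratified sampling — an equal number of reference pixels
(default 300) per mapped class, so rare classes such as forest are not
swamped — followed by an error matrix with overall accuracy (OA),
commission (1 − user's accuracy) and omission (1 − producer's accuracy)
per class. Because equal-allocation sampling biases the raw OA when class
areas are unequal, the error matrix also reports an area-weighted OA
(mapped-area-weighted user's accuracies) and standard errors for both: a
simple-random SE for the raw OA and a stratified SE for the weighted one.

**Coarse-series preparation.** Two 16-day composite streams (Terra-like and
Aqua-like, offset 8 days) of six signals — NDVI, EVI, blue, red, NIR, SWIR —
carry a per-observation reliability flag and the per-pixel compositing DOY.
Processing: (1) merge the streams into an 8-day series ordered by
per-pixel DOY, averaging same-day duplicates; (2) drop observations flagged
snow/ice, cloud or no-data (good and marginal are kept); (3) STL-based
outlier screening (below); (4) Savitzky–Golay smoothing: linear
interpolation to the regular 8-day grid, then a local least-squares
polynomial fit (default order 2, half-window 4 grid steps ≈ 32 days, edges
handled by shrinking the window asymmetrically); (5) seasonal statistics:
mean, min, max, range and standard deviation per signal for spring
(Mar–May), summer (Jun–Aug) and autumn (Sep–Nov) on a non-leap DOY
calendar — 6 × 3 × 5 = 90 predictors. The seasonal sd uses the sample
(n−1) form over the grid points in the season.

**STL outlier screening.** Each signal's gridded series is decomposed and
observations whose remainder exceeds `k_sd` (default 3) robust standard
deviations are discarded. The robust sd is 1.4826 × MAD of the pixel's
remainders, floored at `min_sd = 1e-3` (in reflectance/index units, well
below sensor noise) so that pure decomposition lack-of-fit is never
flagged. Two implementation points deserve note:

* *Batching.* The non-robust STL is an exactly linear map of the input
  series, so the remainder operator is precomputed once per grid length (by
  decomposing identity columns with statsmodels' STL) and applied to all
  pixels as a matrix product; this is verified against per-series STL in
  the tests. A per-series `robust=True` path exists for small data.
* *Single-year series.* STL needs at least two full cycles. Replicating a
  one-year series is not a usable workaround: a replicated series is
  exactly periodic, the seasonal component absorbs everything — spikes
  included — and the remainder degenerates to numerical lack-of-fit, which
  the MAD-relative rule then misreads (in experiments it discarded ~80% of
  good observations). For series spanning fewer than two cycles the
  remainder is therefore taken against a loess trend fit (window ≈ period/5
  grid steps): for a single year, the annual trajectory *is* the seasonal
  signal. The thresholding rule is unchanged. Screening is computed per
  signal; an observation flagged for any signal is excluded for all
  signals, since the series carries one reliability state per observation.
* *Spike leakage.* Even with ≥ 2 cycles, part of an isolated spike leaks
  into the seasonal component, and at small cycle counts the spike's
  phase-mate slots in other cycles can also cross the threshold. This is a
  property of STL screening itself, not of the implementation; the tests
  pin the behaviour against statsmodels directly.

**Fraction regression.** The best fine-resolution land-cover map provides
reference fractions: per coarse pixel, the proportion of constituent fine
pixels in each forest class (missing fine pixels leave the denominator;
pixels over 50% missing are dropped). Training locations are drawn by
greedy random thinning with a 1000-m minimum distance to limit spatial
autocorrelation. One regression forest per forest type (same forest
settings) maps the 90 seasonal features to type fractions; predictions are
clipped to [0, 1] and overall forest cover is the clipped sum of the three
types. Fractions are represented in [0, 1] internally; reports render
percent.

**Validation.** Strata are defined on the *predicted* map: overall fraction
> 0 (forest) versus exactly 0 (non-forest); up to 1000 pixels per stratum
are drawn, and per target (three types + overall) the report gives
Pearson's r and the normalized root-mean-square error

    NRMSE = sqrt( Σᵢ (Pᵢ − Rᵢ)² / n ) / R̄ ,

with Pᵢ predicted, Rᵢ reference, and R̄ the mean reference over the sample.
R̄ = 0 renders NRMSE undefined (reported as NaN, not an error). An empty
stratum (e.g. no pixel predicted exactly 0) is tolerated.

**Map comparison.** Continuous tree-cover maps are harmonized (a 2000
baseline updated by loss → 0% and gain → 100%, loss winning conflicts — the
conservative choice for end-of-decade cover; forest/non-forest translation
by a strict > 30% threshold) and degraded by nodata-aware block-mean
aggregation with trailing partial blocks dropped (padding would bias edge
means). At each scale, agreement is Pearson's r and an OLS slope over
pixels where either map reports cover > 0 (union mask); the regression
direction is configurable because published slopes rarely state it, with
the default regressing the comparison map on the reference-role map.
Zonal summaries give per-zone percent cover (mean fraction × 100).

## The synthetic-scene generator

The generator defines the study conditions; it is deliberately simple and
fully seeded (every draw derives from the landscape seed, so identical
configurations are bit-identical).

* **Landscape**: white noise smoothed with a Gaussian kernel
  (σ = `patch_scale`, default 12 fine pixels) and quantile-sliced at the
  cumulative class weights — realized proportions match targets to integer
  rounding. Default weights: 10% deciduous, 10% evergreen, 8% mixed forest,
  10% wetland, 27% herbaceous, 25% barren, 10% water (≈ 28% forest), a
  forest-rich dryland mosaic that keeps every class abundant enough for
  stratified assessment at desk scale.
* **Phenology**: each class interpolates between a dormant and a peak
  endmember spectrum along a double-logistic greenness curve
  g(d) = logistic(k(d − d_up)) − logistic(k(d − d_down)). Parameters were
  chosen once to reproduce the separability structure that motivates
  temporal metrics: deciduous forest and herbaceous land nearly coincide
  spectrally in mid-summer but differ in green-season timing and length;
  mixed forest lies between deciduous and evergreen; barren and water are
  aseasonal. Per-observation Gaussian noise (fine bands sd 0.04; coarse
  signals sd 0.008–0.015) keeps single-date classification visibly
  imperfect without destroying metric-based separability.
* **Fine acquisitions**: 16-day revisit alternating two sensors, the second
  carrying SLC-off-style periodic diagonal stripe gaps; cloud cover per
  acquisition ~N(0.35, 0.15) realized as spatially correlated blobs
  (quantile-thresholded smoothed noise); winter snow blobs. Not-clear
  positions store NaN so any computation that ignores the QA mask poisons
  its output ("mask honesty").
* **Coarse composites**: exact 8×8 nesting of fine pixels (240 m), i.e. no
  point-spread or resampling effects; per period the signal is the
  area-weighted mean of class curves at a per-pixel random DOY within the
  period, plus noise; reliability flags drawn with probabilities 10%
  marginal, 8% cloud, 4% snow, 2% no-data. EVI is generated from its own
  curve parameters rather than derived from bands, mirroring how both
  indices arrive pre-computed in 16-day composite products.

What the generator does *not* emulate — radiative transfer, topography,
BRDF/illumination effects, geolocation error, sensor point-spread functions,
spatially correlated noise in the coarse stream, label noise in training
data. Passing tests therefore demonstrate that the pipeline recovers known
fractions *when its assumptions hold*, not that real-archive accuracies
would match.

## The desk-scale study

`drycover.study.run_study` executes the full chain on 10 replicates of a
512 × 512 fine grid (coarse factor 8 → 64 × 64 coarse pixels, 3 years × 23
acquisitions). To keep a replicate around half a minute on one CPU the
study uses 100 trees and 400 training pixels per class (the library
defaults remain 1000 trees; OA and NRMSE estimates are insensitive to the
difference at these sample sizes). The 1000-m minimum distance on a 64 × 64
grid of 240-m pixels caps fraction training at ≈ 160 samples — the
spatial-thinning trade-off at desk scale. Summaries are means over seeds
for accuracies and medians for error/correlation metrics.

Expected qualitative outcomes, mirroring the structure reported for the
real-archive workflow: OA(epoch metrics) ≥ OA(1-year metrics) ≥
OA(single-date); overall-forest NRMSE strictly smallest among the four
fraction targets (type-level predictions inherit confusion between
spectrally similar forest types, which cancels in their sum), with mixed
forest worst; predicted vs. true overall fraction r ≥ 0.9; map-pair
agreement non-decreasing under aggregation. The agreement experiment uses a
smooth synthetic cover field (200 × 200, correlation length ≈ 15 px) plus
i.i.d. noise (sd 10 percentage points), compared at native, 4× and 20×
aggregation.

## Numerical conventions and edge cases

* Percentiles: linear interpolation between closest ranks; standard
  deviation: sample (n−1) form; a single observation yields sd = 0. Note
  that neither convention is invariant to replicating observations, so
  pooling identical years changes sd and percentiles slightly (mean and
  median are invariant).
* Compositing requires ≥ `min_obs` (default 3) clear observations for
  metrics; pixels below that, or with no clear observation for the
  single-date composite, are flagged missing, excluded from training, and
  classified as missing rather than imputed.
* Savitzky–Golay requires poly_order < window length and ≥ poly_order + 1
  valid observations per pixel; short series render the pixel missing.
* Vote ties (classification) resolve to the lowest legend code; equidistant
  DOY ties to the earlier acquisition; duplicate same-day coarse
  observations are averaged pairwise (exact for the two-sensor case).
* Degenerate inputs follow documented contracts rather than erroring where
  the field's workflows tolerate them: absent classes yield zero samples
  with a warning; all-flagged series yield missing pixels; constant inputs
  yield undefined (NaN) correlations.

## Known limitations

* No geographic referencing: rasters are plain TIFF plus JSON sidecars and
  grids must nest by construction; reprojection between real products is
  out of scope.
* The classification reference in the synthetic study is the ground-truth
  raster itself (a perfect interpreter); real reference labelling adds
  error that is not modelled.
* STL screening of single-year series detects isolated spikes via the loess
  fallback but cannot separate a genuine one-year seasonal anomaly from an
  outlier; multi-year series should be preferred where screening matters.
* The fraction model is model-based inference; no design-based area
  estimates or per-pixel uncertainty layers are produced.
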