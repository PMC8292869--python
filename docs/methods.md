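# Methods

This note records the model, the conventions that make the pipeline
bit-reproducible, and the design choices taken where the underlying
workflow (a MaZda/B11-style texture analysis) leaves details open.

## Region normalization

All texture statistics are computed on integer gray levels produced by
windowing the in-mask intensities to `[mu - 3*sigma, mu + 3*sigma]` and
mapping linearly to `1..Ng`:

```
level = floor((clip(v) - lower) / (upper - lower) * Ng) + 1,   v = upper -> Ng
```

* `mu`, `sigma` are the in-mask mean and **population** SD (divisor `n`);
  a fixed convention is required for exact reproducibility.
* `Ng = 64` (6-bit) by default — the granularity the co-occurrence and
  run-length definitions presuppose; it is exposed in config
  (`quantization.levels`). All six families consume the same quantized
  raster.
* Out-of-window intensities are **clipped, not discarded**, so the ROI
  geometry (run structure, AR neighborhoods) is preserved.
* A constant ROI has zero window width; it maps to level 1 everywhere and
  downstream moments that need spread are reported NaN with a warning.

The windowing is the reason features are invariant to
brightness/contrast changes `v -> a*v + b` (`a > 0`): `mu` and `sigma`
transform covariantly, so the levels are unchanged (up to ties exactly on
quantization boundaries).

## Feature families and conventions

275 features in a fixed order (9 histogram + 5 gradient + 220
co-occurrence + 20 run-length + 5 AR + 16 wavelet). Fixed conventions:

* **Moments** are population moments; skewness is `m3/m2^1.5`, kurtosis the
  uncorrected `m4/m2^2`. Percentiles are nearest-rank.
* **Gradient**: central differences (half the two-neighbor difference),
  evaluated only where all four 4-neighbors are in-mask.
* **Co-occurrence**: offsets `(d,0), (0,d), (d,d), (d,-d)` for `d = 1..5`,
  named `S(dx,dy)` with `dx` = columns rightward, `dy` = rows downward.
  A pair is counted only when both pixels are in-mask; matrices are
  symmetrized and normalized. Entropies use the natural log with
  `0*log 0 = 0`. `Correlat` is NaN when the marginal SD is zero.
* **Run-length**: maximal same-level runs along horizontal, vertical, 45°
  and 135° lines; the mask boundary breaks runs; `Fraction` divides the
  run count by the in-mask pixel count.
* **Autoregressive model**: causal neighbors `(x-1,y), (x-1,y-1), (x,y-1),
  (x+1,y-1)` on mean-centered levels, least squares, at least 50 complete
  equations required; `Sigma` is the RMS residual **in level units**
  (multiply by the window width over `Ng` to return to intensity units).
* **Wavelets**: Haar transform of the ROI bounding box with out-of-mask
  pixels filled by the in-mask mean (minimizes spurious edge energy; the
  reference software's handling is undocumented, so this is our
  convention). At each scale the current approximation is cropped to even
  dimensions, making the 2x2 Haar blocks orthonormal: subband sums of
  squares reproduce the input energy exactly, which the tests assert.
  `WavEnXX_s-N` is the mean squared coefficient; the first subband letter
  is the filter along columns (HL = column-difference band).

Numeric identity with the MaZda program is *not* claimed: its exact AR
neighbor set, wavelet windowing, and feature-count bookkeeping are not
published. The families above are implemented in their standard published
forms and validated against independent brute-force enumerators (exhaustive
pair counting and run scanning) to 1e-12.

## Segmentation

Interactive level-set delineation is replaced by seeded region growing
with fully specifiable semantics: from the seed, 4-connected pixels are
admitted while `|I - mu_region| <= tolerance * max(sigma_region,
sigma_floor)` (running statistics, `tolerance = 3` matching the mu+/-3sigma
spirit, `sigma_floor = 2` intensity units so growth can start from a single
pixel) **and** the local gradient magnitude stays below `gradient_ceiling`
(10 intensity units/px), followed by morphological closing (radius 2 px) to
seal pixel-scale leaks. Growth that reaches more than half of the image
border raises a runaway error (no enclosing boundary exists — e.g. a
uniform image). Note that on an ideal step edge the rim pixel itself
carries the large gradient, so the gradient stop erodes roughly one
boundary pixel; closing restores most of it, and on default synthetic
effusions the Dice overlap with the generating mask is about 0.96. Masks
can always be supplied externally, bypassing this module.

## Feature selection, classification, inference

* **Fisher coefficient** `F = sum_k P_k (mu_k - mu)^2 / sum_k P_k s_k^2`
  with class priors equal to class frequencies and population variances;
  zero pooled within-class variance gives `+inf` (separated means) or 0.
* **POE** is the resubstitution error of the best single-feature threshold
  rule (thresholds at midpoints of sorted unique values, both polarities,
  majority rule included) — exactly computable, and the simplest faithful
  reading of "probability of classification error". **POE+ACC** uses unit
  weights; an undefined correlation (constant feature) contributes 0. All
  ties break lexicographically by feature name, so selections are
  bit-reproducible.
* **k-NN**: `k = 1` with leave-one-out validation (the validation protocol
  of the reference software is not published; 1-NN + LOO is the
  convention and is parameter-free). Features are standardized to
  population z-scores; distance ties break by sample order, vote ties
  toward the benign label. Positive class = malignant.
* **Mann-Whitney U** uses midranks; p-values are exact by full enumeration
  for `n1 + n2 <= 12` without ties, otherwise the normal approximation
  with tie and continuity corrections (the continuity shrinkage is clamped
  at zero so identical groups give exactly p = 1).
* **Bonferroni** denominator = total number of selected features counted
  with multiplicity across both sets (2 x 10 = 20 even when the sets
  overlap), reproducing the corrected threshold 0.05/20 = 0.0025.
* **ROC**: AUC from the same rank computation (`AUC = U/(n1 n2)`, ties
  half); 95% CI and the AUC = 0.5 test from the DeLong placement-value
  variance; cutoff maximizes the Youden index over observed values with
  the "> cutoff" rule, ties resolved toward higher specificity (J is
  compared after rounding to 12 decimals to avoid float-noise ties).
* **Proportion CIs** are exact Clopper-Pearson beta-quantile intervals;
  these reproduce printed intervals such as 22/23 -> (78.1, 99.9)% and
  13/29 -> (26.4, 64.3)%.

## Synthetic cohort generator

The generator emulates the *statistical* contrast the analysis assumes,
on an HU-like scale (fluid means near 0-30, background 60), without
claiming anatomical or Hounsfield fidelity:

* **benign-like (heterogeneous)**: 5 Voronoi compartments with mean
  offsets ~ N(0, 8 HU) plus nearly-white noise (SD 6, correlation length
  0.5 px) — a mixed, multi-density, rough fluid;
* **malignant-like (homogeneous)**: a single smooth correlated field
  (SD 6, correlation length 6 px) — locally homogeneous fluid.

Default cohort: 29 benign + 23 malignant, 128x128 px, elliptical ROIs with
semi-axes uniform in [18, 40] px (minimum transverse diameter 30 px,
mirroring the 30 mm inclusion criterion). One master seed; each sample
derives its own seed, so cohorts are bit-identical across runs.

The correlation-length pair (0.5 vs 6 px) was chosen so that local
homogeneity is unambiguously the planted between-class contrast: with it,
the homogeneous class shows higher mean S(4,4)InvDfMom and an
InvDfMom-family feature enters the Fisher top ten in 40/40 replicates on
two disjoint seed families. Because mu+/-3sigma windowing normalizes each
sample by its *global* spread, the heterogeneous class's compartment
variance compresses its local noise into few levels; the roughness of its
noise field must therefore exceed the homogeneous class's by a wide margin
for the local-homogeneity contrast to survive normalization — this is also
why per-pixel feature maps only show the class contrast once the map
window is wide enough (radius >= 12 px) to straddle compartments.

What passing tests on this cohort do **not** show: real effusions differ
by far subtler margins (reported medians 0.079 vs 0.084 for
S(4,4)InvDfMom), contain acquisition artifacts, partial-volume rims and
scanner-dependent noise spectra, and are not elliptical. The synthetic
study validates the *machinery* (direction of effect, selection behavior,
classifier plumbing), not clinical effect sizes; the saturated accuracy on
synthetic cohorts carries no clinical meaning.

## Problem sizes

The test suite and the acceptance script use 20 replicates of the default
52-sample cohort (1040 images), 100-image brute-force oracle sweeps on 6x6
rasters, 200-permutation nulls for the classifier, and a 128x128 AR
fixture; the full suite runs in well under a minute on one CPU core.

## Known limitations

* Single-slice 2-D analysis only; no 3-D texture, no multi-slice ROIs.
* No gray-level size-zone / NGTDM families; no IBSI-certified definitions.
* The AR and wavelet conventions are ours where the reference software is
  undocumented; coefficients are comparable within this package, not
  across implementations.
* DeLong CIs and the AUC = 0.5 test are asymptotic; with 23 + 29 samples
  they are adequate but not exact.
* The segmentation stand-in is a region grower, not a PDE level set; it
  assumes a roughly uniform fluid pool enclosed by a gradient boundary.
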