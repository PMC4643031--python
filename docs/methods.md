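# Methods

This note documents the models, conventions and design choices behind
`lulcfuse`, in the order the pipeline runs them.

## Feature extraction

**Vegetation indices.** NDVI = (NIR − red)/(NIR + red);
EVI = G·(NIR − red)/(NIR + C1·red − C2·blue + L) with the standard
coefficients G = 2.5, C1 = 6, C2 = 7.5, L = 1. Both are clipped to
[−1, 1]; zero (NDVI) or near-zero (EVI, |denominator| ≤ 1e-6)
denominators yield nodata.

**QA weighting.** Composite quality flags map to fitting weights
1.0 (QA 0, good), 0.5 (QA 1–2, marginal), 0.1 (QA 3, cloudy). Cloud
contamination biases vegetation indices downward, which motivates both the
low weight and the upper-envelope fit below.

**Seasonal model and upper-envelope fit.** The per-pixel seasonal curve is
a single asymmetric Gaussian
`f(t) = base + A·exp(−(t−t_p)²/(2σ²))`, with σ = σ_left before the peak
and σ_right after — five parameters per pixel. It is fitted to the VI
series by weighted least squares (a vectorized Levenberg–Marquardt across
all pixels simultaneously, 40 damped iterations from a moment-based start,
σ clamped to [4, 400] days and A ≥ 0). Two envelope-adaptation passes
follow the initial fit: each halves the weight of points lying below the
current curve and refits, so the curve converges onto the upper envelope
of the good observations. Pixels with fewer than 6 valid composites are
returned as nodata; a series whose every weight sits at the cloud minimum
is fitted anyway with a warning. The choice of a single-season model is
deliberate: double-cropping phenologies are out of scope.

**Phenology metrics** (11 per pixel) come from the fitted curve evaluated
on a daily grid — the model is continuous, and extracting from the 16-day
composite chords would bias the peak and amplitude low by several percent
for narrow seasons. Season start/end are the first/last days the curve
crosses `base + f·amplitude` with season fraction f = 0.2 (a common
threshold choice; configurable); the mid-season date is the curve maximum;
`base` is the mean of the pre-peak and post-peak minima; rates of
increase/decrease are slopes between the start/end crossings and the
half-amplitude crossings, expressed in VI units per composite interval;
the large integral is the area under the curve between start and end and
the small integral the area above the base level (VI·days). Curves with
amplitude below 0.05 VI units carry no detectable season: their metrics
are imputed (dates at the window midpoint, amplitude/rates/integrals 0,
base and peak at the series mean) so the feature matrix stays rectangular,
and a quality flag is available as an optional extra column.

**Growing-season statistics.** Mean, standard deviation (sample, ddof = 1;
0 for a single observation), minimum, maximum and range of each band/VI
over valid composites in a day-of-year window. The window defaults to DOY
97–297 (April–October), a temperate-zone growing season; it is
configurable because no universal definition exists.

**Terrain.** Slope (degrees) and aspect (degrees clockwise from north) by
Horn's 3×3 finite differences with edge replication at borders; flat cells
get the aspect sentinel −1. Aspect enters the classifiers as raw degrees;
a circular (northness/eastness) encoding would be statistically cleaner
but raw degrees are kept as the default predictor set, matching common
practice in regional LULC work.

**Feature combinations.** C1 = 6 bands/VIs × 5 statistics + 3 terrain =
33 features; C2 = 11 phenology + 3 terrain = 14; C3 = union = 44 (terrain
counted once). Composites are sorted by date on construction, so features
are invariant to input order. Any residual NaNs after assembly are imputed
with per-feature medians.

## Classifiers

Five backends behind one train/predict interface, all exposing full
class-membership probability vectors:

| kind | backend | probabilities | scaling |
|------|---------|---------------|---------|
| rf   | random forest, 500 trees, mtry = ⌊√p⌋ | tree-vote fractions | none |
| svm  | RBF SVM, C = 10, γ = 1/p | pairwise Platt-coupled sigmoids | z-score |
| wknn | k = 11, triangular kernel, Euclidean | normalized kernel-weighted neighbour frequencies | z-score |
| ann  | one hidden layer of ⌊2p/3⌋ units, ≤ 500 iterations | softmax | z-score |
| nb   | Gaussian naive Bayes, variance floor 1e-9 | posteriors | none |

Defaults are ecosystem-standard settings, all overridable per experiment;
`tune_hyperparameters` provides a stratified cross-validated grid search
maximizing kappa. Distance/margin methods are standardized on training
data; tree and Bayes methods are not. Missing feature values at predict
time are imputed with training-set medians. k for WKNN is truncated (with
a warning) when the training set is smaller than k.

One caveat worth knowing: for the SVM, the argmax of the Platt-coupled
probabilities can occasionally differ from the decision-function vote of
the underlying machine (typically a few percent of borderline samples).
The pipeline consistently uses the probability argmax, which is the
quantity the Bayesian fusion needs.

Stratified splitting assigns `round(0.7·n)` points per class to training
(half-up, clamped so both splits stay non-empty) — e.g. 186 points split
130/56.

## Fusion and uncertainty

Bayesian averaging is the equally weighted mean of the K member
probability vectors; the fused label is its argmax, with exact ties (a
measure-zero event in practice) resolved to the lowest class code and
counted. Accuracy-weighted averaging exists behind the equal-weight
default but is off. Bayesian fusion never emits unclassified pixels;
low-confidence screening is done downstream by thresholding the CMP layer
(the per-pixel maximum fused probability, in [1/M, 1]), by convention at
0.3/0.4.

Majority vote requires a strict plurality of at least 2 of K votes;
pixels with no common vote — or, for even K, a tie among top counts — are
unclassified with vote count recorded as 1. Nodata in any member makes
the pixel nodata.

Diagnostics: vote-count and CMP maps, CMP histograms with above-threshold
fractions (0.4, 0.5), per-class proportion ratios inside uncertain subsets
(classes with ratio > 3 are flagged as hard to recognize), and the
Pearson correlation between per-class mean CMP and per-class PA/UA
(defined only with ≥ 3 classes and non-degenerate variance).

## Accuracy statistics

The confusion matrix is predicted × reference with an optional
unclassified row. Producer's accuracy denominators include unclassified
predictions (an unclassified reference point is an omission); user's
accuracy is undefined for the unclassified row. Kappa is computed on the
full matrix with the unclassified row as a predicted category whose
reference margin is zero — this matches the reference benchmark tables
within their printed rounding — and is switchable to dropping unclassified
samples. Reported percentages round half-up to one decimal; full precision
is kept internally.

The sample-size sensitivity experiment draws an independent stratified
subsample (without replacement, floored at one point per class) for every
(replicate, fraction) pair, retrains each backend and evaluates on the
fixed test set; subsamples are shared across backends within a replicate
so curves are comparable.

## Change detection

The conversion matrix cross-tabulates commonly valid pixels between two
dates, scaled by the pixel footprint (0.0625 km² on a 250 m grid, taken
from the geotransform and overridable); unclassified/nodata pixels are
excluded and reported as a remainder. Net conversion from class a to a
class set B is the forward area minus the reverse flow; per-class area
change compares row and column margins. Classes absent from a map remain
as zero rows/columns so matrices keep a stable shape.

## Synthetic scenes

The generator emulates the input stack of a composite-VI classification
study. Label maps are the per-pixel argmax of independent smoothed
Gaussian random fields (correlation length 5 pixels by default), which
yields contiguous patches resembling a mosaic landscape and guarantees
seedable determinism. Per pixel, the NDVI trajectory is the class's
asymmetric-Gaussian curve plus N(0, 0.02) noise; composites are
independently cloud-contaminated with probability 0.15 (QA 3, VI biased
downward by a uniform fraction up to 50%) and flagged marginal with
probability 0.10 (QA 1–2). Reflectances are back-solved from the NDVI
definition at a class-specific brightness (blue = red/2; MIR tracks red),
so recomputing NDVI/EVI from the simulated bands closes the loop. The DEM
is a smooth random surface (sd 200 m around 1200 m) shifted by per-class
elevation affinities. The default class signatures sketch a temperate
agro-pastoral mosaic: crops with a narrow intense season, deciduous forest
broad, evergreen forest high-base/low-amplitude, shrublands and grassland
intermediate, and bare/urban/water spectrally flat, separated by
brightness and NDVI sign.

What the simulation does *not* emulate: mixed pixels (heterogeneity arises
only at patch borders), radiative transfer, inter-annual variability,
georeferencing error, and the class-overlap structure of real landscapes.
The default classes are more separable than real land cover, so ensemble
accuracies on synthetic scenes sit near the ceiling (~99% OA rather than
the high-80s typical of real regional maps). Passing tests therefore
demonstrate the correctness and stability of the machinery — fusion at
least as accurate as the mean member, monotone benefit of training data,
parameter recovery under noise and clouds — not field-realistic accuracy
levels.

Reference points are sampled stratified from pixels whose 3×3
neighbourhood is single-class, mirroring the practice of discarding
reference points in spatially heterogeneous neighbourhoods.

## Problem sizes and numerical choices

Replicated experiments run at desk scale: ensemble trials use 192×192
scenes with 572 points per class (70% split → 400 training points per
class) over 20 seeds in the test suite (12 in the acceptance script),
requiring the target property in ≥ 90% of seeds; sensitivity checks use
96×96 scenes with 120 points per class at fractions {0.1, 1.0} × 5
replicates; phenology recovery uses 150 pixels per class on three
clearly seasonal classes. Tolerances: probability simplexes to 1e-6;
integer raster round trips bit-exact, float rasters to 1e-6 (32-bit
storage); kappa limit checks to 1e-10; benchmark table reproduction to
0.05 percentage points (their printed precision); net flows to 1 km²
(two published flows differ from their own matrix arithmetic by 1 km²).

## Known limitations

- Single-season phenology only; no harmonic or double-logistic
  alternatives.
- Aspect as raw degrees wraps at north; the optional northness/eastness
  encoding is provided but off by default.
- SVM probability/decision-function disagreement on borderline samples
  (see above).
- The Bayesian-average argmax tie rule (lowest code) is arbitrary but
  deterministic; ties are counted and logged.
- No area-weighted (design-based) accuracy or error-adjusted area
  estimation; no McNemar tests between classifiers.
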