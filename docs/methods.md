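# Methods

This note documents the models, conventions and numerical choices behind
`texnac`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Kinetic model

A dynamic series is one pre-contrast frame plus post-contrast frames with
strictly increasing acquisition times (default Δt = 60 s, six frames).
Enhancement is always `frame[t] − frame[0]`.

* **Subtraction sign.** Clinical descriptions of "residual" subtraction
  images sometimes phrase the operation as pre-minus-post; we compute
  post − pre so that enhancement is positive, consistent with positive
  amplitudes and upward-sloping uptake curves.
* **Amplitude** is the maximum *absolute* enhancement (arbitrary units,
  AU) over the post-contrast points — no percent-over-baseline
  normalization. Adding a constant to all frames changes nothing
  (baseline invariance).
* **Wash-in** is the slope between the enhancement peak and the
  preceding time point (AU/s); **wash-out** is the ordinary-least-squares
  slope over the final three (time, signal) points, reported *signed*
  (a positive value is a still-rising delayed phase). Ties at the peak
  resolve to the earliest frame, deterministically.
* Kinetic ROIs smaller than ten pixels are flagged (warning by default,
  error in strict mode); per-pixel kinetic maps apply exactly the same
  definitions to single-pixel curves.

## Texture conventions

Images are min–max quantized *within the analysed mask* into `2**bits`
grey levels (default 5 bits, 32 levels), making every downstream feature
invariant under positive affine intensity rescaling. A constant ROI maps
to level 0 everywhere (valid, degenerate input).

The co-occurrence matrix counts ordered pixel pairs at distance 1 along
the four main directions (0°, 45°, 90°, 135°), symmetrized and pooled
into one matrix before normalization (averaging directional matrices and
summing them coincide after normalization). Only pairs fully inside the
mask count. Feature formulas index grey levels 1..G (the classical
convention; this affects sum average/variance but not contrast, energy,
entropy or correlation). Entropy uses log base 2. For a constant ROI the
correlation denominator vanishes; correlation is defined as 0 with a
warning rather than NaN.
`sum_variance` is centred on `sum_average` (one of the two historical
variants; fixed here). `difference_variance` is the variance of the
grey-level-difference distribution.

The run-length matrix decomposes every maximal in-mask collinear pixel
sequence of the same four directions into maximal equal-level runs; runs
break wherever the line leaves the mask, so irregular ROIs are handled
exactly. Run-level weights index levels 1..G so the low-grey-level
emphases never divide by zero. Run percentage divides the number of runs
by the in-mask pixel count summed over the directions used. Published
tables from older third-party texture code often renormalize feature
scales (e.g. entropy printed on a 0–255-like scale, SRE ≪ 1); `texnac`
reports the raw standard formula values and offers 0–255 scaling only in
the sliding-window `texture_map` display (3×3 neighbourhood by default,
clipped at the border, quantized within the window).

## Segmentation

Inside a rectangular search box the per-pixel amplitude and wash-in are
z-scored (they carry different units) and partitioned by k-means with
k = 2, best of `n_replicates` random restarts; the cluster with the
higher mean raw amplitude is the lesion. A morphological opening with a
disc structuring element (radius 1 by default) removes isolated pixels,
and the largest 4-connected component is returned. Cluster count k = 2
is part of the method, not a tunable. The order opening → largest
component is an interpretation choice; both orders give identical
results on compact lesions.

A behaviour worth knowing: at *low* noise the per-pixel wash-in is
bimodal over the lesion — when the noisy per-pixel maximum occasionally
lands on the post-peak plateau, wash-in collapses to ≈ 0 for that pixel —
and 2-means may carve those pixels off, so Dice against ground truth is
not monotone in the noise level (≈ 0.95 at σ = 1 AU, ≈ 0.998 at σ = 4,
degrading only beyond σ ≈ 10 for a 75 AU lesion). This is a property of
the peak/plateau tie in the kinetic definition, not a numerical defect.

## Statistics

* **Mid-P Fisher.** One-sided mid-P in each tail is P(more extreme) +
  ½·P(observed) under the hypergeometric null; the two-sided p doubles
  the smaller tail, capped at 1. This doubling convention (rather than
  probability-ordering summation) is the one that reproduces the
  emulated study's printed table of biomarker p-values from its printed
  counts, and is fixed here. Zero-margin tables return p = 1 with a flag.
* **Wilcoxon rank-sum** uses midranks, tie-corrected variance and
  continuity correction (normal approximation); **D'Agostino–Pearson**
  is the K² omnibus test (χ², 2 df), requiring n ≥ 8.
* **ROC.** Empirical curve over all thresholds; AUC equals the
  normalized Mann–Whitney statistic with half credit for ties. The
  cut-off maximizes Youden's J, ties broken toward higher sensitivity
  (non-response detection is the priority). Orientation is chosen
  automatically per feature so AUC ≥ 0.5, with the direction recorded.
  The AUC = 0.5 test is the Mann–Whitney normal approximation; pairwise
  AUC comparison uses DeLong placement-value covariance. The exact
  AUC-comparison procedure of the original analysis is not recoverable;
  DeLong is the documented substitute.
* No multiple-testing correction is applied anywhere, by design.

## Prediction

Features are z-scored per training fold; optional natural-log transforms
(with a training-fold-driven positivity offset) are likewise fitted on
the training patients only. LOOCV predicts each patient from a model
trained on the other n − 1 — including all preprocessing — so no
information leaks from the held-out case.

The unsupervised classifier is 2-means with the L1 (city-block)
distance: each replicate starts from two distinct training observations,
Lloyd iterations assign by L1 distance and update centroids as
coordinate-wise medians, and the lowest-dispersion replicate of 30 wins.
Clusters take the majority training outcome; ties break toward NR
(sensitivity priority). The supervised classifier is maximum-likelihood
logistic regression (NR when P ≥ 0.5) with a mild ridge fallback under
separation, flagged by a warning.

The subset search enumerates all feature combinations in a size range
and ranks by accuracy, ties toward sensitivity, then smaller subsets,
then lexicographically. The full 2–26-parameter enumeration is 2²⁶ − 27
≈ 6.7 × 10⁷ LOOCV evaluations; the search refuses ranges beyond a cap
(default 10⁶) unless forced, reporting the count.

## Synthetic-data generator

The generator is the package's test bed: it produces data with exactly
the structure the analysis measures, so every stage can be verified
against ground truth without patient images.

* **Enhancement curves** are piecewise-linear — zero at the pre-contrast
  frame, linear rise to the configured amplitude at a configurable peak
  frame (the last rising segment carries the configured wash-in slope),
  then a linear tail with the wash-out slope. This keeps ground truth in
  exactly the measured parameterization; no pharmacokinetic model is
  implied and none of the quantities are interpretable as transport
  parameters. A positive tail slope would relocate the curve maximum to
  the final frame, so the default wash-out is −0.04 AU/s (the magnitude
  seen in published group medians, with the sign chosen for
  identifiability of the peak; the published medians do not separate the
  response classes on wash-out, so planted class differences are
  unaffected).
* **Geometry.** Single 2D slice (64×64 default): an elliptical "mass"
  or a patchy "non-mass" lesion (random-field threshold inside the
  ellipse support), weakly enhancing parenchyma (amplitude 12 AU), a fat
  compartment near baseline (smooth-field threshold, 30 % of the grid by
  default), additive zero-mean Gaussian noise (σ = 2 AU) on every frame.
  Gaussian rather than Rician noise: the analysis operates on subtracted
  high-SNR images where the distinction is immaterial.
* **Texture heterogeneity** multiplies the lesion curve pixel-wise by
  exp(σ·G) with G a unit-variance Gaussian random field of configurable
  correlation length (σ = 0.4 by default). Longer correlation → smoother
  lesion → higher homogeneity/IDM, lower entropy. Because quantization
  is min–max within the mask, a field much smoother than the lesion size
  shrinks the in-mask range until the additive noise dominates the grey
  levels, so measured homogeneity responds to correlation length
  monotonically only up to a few pixels on ~15-pixel lesions; the
  defaults sit inside that responsive regime.
* **Cohorts** default to the emulated study size (19 NR / 36 PR / 14 CR).
  Class labels are fixed by the counts; biomarkers (subtype categorical;
  ER, PgR, Ki67 > 14 %, HER2, mass flags independent given class) are
  drawn from the study's observed class-conditional frequencies.
  Non-responder lesions are generated with a longer texture correlation
  length (+2.5 px on a 1.0 px base), lower wash-in (−0.09 AU/s) and
  slightly lower amplitude (−7 AU) — the directions reported for the
  real cohort's group medians. The magnitudes are this package's own
  calibration: the source study reports no effect sizes measurable
  without its images, so the defaults were chosen to make the planted
  effect clearly detectable at the study's sample size by the
  unsupervised classifier (the generator's design contract), while
  per-patient lognormal scatter (8 % on kinetics and geometry) keeps the
  cohort from being trivially separable. With these defaults the
  4-feature k-means model reaches LOOCV sensitivity ≈ 75–100 %
  (mean ≈ 88 % over cohort seeds) — the 2-means classifier occasionally
  locks onto class-orthogonal variance and under-performs on unlucky
  cohorts, which is an honest property of unsupervised classification.
  Setting the class-effect shifts to zero yields chance-level prediction.
* **What passing tests show.** The generator emulates the *statistical
  shape* of the problem, not breast MRI realism: no coil or bias-field
  artefacts, no motion, no DICOM semantics, no partial-volume effects,
  no 3D structure, and biomarkers that are statistically independent of
  the image given the class. Pipeline performance on these phantoms
  validates the machinery (feature definitions, cross-validation
  hygiene, statistics); it says nothing about clinical accuracy on
  patients.

## Problem sizes used in the checks

Texture oracles run on 200 random masked 8–16 px images; ROC identities
on 100 random data sets plus 10⁴ permutations; the planted-signal
prediction checks use full-size 69-patient cohorts at three fixed seeds
with a 1000-permutation null (5 classifier replicates per permutation,
30 for the headline evaluation). Segmentation recovery uses noise-free
and σ = 5 AU phantoms (uniform 75 AU lesions).

## Known limitations

* Exhaustive 2²⁶-subset search with LOOCV is deliberately capped; the
  package is honest about what is desk-scale.
* The k-means classifier's cluster-to-class mapping needs both classes
  in every training fold and can be unstable on weakly structured data
  (see above).
* Published feature magnitudes from renormalizing third-party texture
  codes are not reproduced — only the standard formula values.
* The phantom's piecewise-linear curve family cannot represent a curve
  whose maximum precedes a rising tail; configured positive wash-out
  values are accepted but the measured peak then moves to the last frame.
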