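# Methods

This note documents the models, conventions and design choices behind
`kernrad`, in the order the pipeline runs.

## Annotation scanning

The input per subject is a pair of images: an exported copy carrying a
closed pure-red annotation curve around the solid tumor region, and the
untouched grayscale original.  A pixel counts as annotation when
R ≥ 200, G ≤ 80 and B ≤ 80 (8-bit); the thresholds are configurable
(`RedRule`) and deliberately loose so that JPEG chroma bleed around a
saturated red line is still captured.  The contour is accepted as closed
when, after a 3×3 morphological closing (which bridges 1-px compression
gaps), it forms a single 8-connected component enclosing a nonempty
interior; otherwise a contour error is raised.

Two 64×64 window placements are provided.  `paper_scan` emulates a raster
scan with step 1 from the top-left: the returned window is the first one
in row-major order containing an annotation pixel.  This is computed in
closed form (smallest feasible top row, then smallest feasible left
column) and verified in the tests against exhaustive enumeration of every
window.  Because first contact places the contour at the window's edge,
the window only covers the whole lesion when the lesion sits near the
image's top-left corner; the default mode is therefore `centroid`, which
centers the window on the centroid of the red bounding box (clipped to
the image).  Windows are 0-based, row-major, half-open:
[top, top+64) × [left, left+64).

The patch is always cut from the non-annotated original so the red line
cannot leak into the features.  The mask is the hole-filled closed
contour with the contour-line pixels themselves erased, restricted to the
window; if window clipping splits the region the largest component is
kept.  RGB originals are converted with luma weights 0.299/0.587/0.114,
rounded to nearest integer.

## Feature registry

Exactly 670 features per (patch, mask) pair, in a fixed manifest order:

* 14 shape descriptors from the binary mask (area, perimeter,
  compactness P²/A, circularity 4πA/P², eccentricity, elongation
  1 − minor/major, axis lengths, equivalent diameter, solidity, extent,
  convexity, boundary roughness, maximum Feret diameter), computed via
  `skimage.measure.regionprops`;
* 8 channels — the original patch, the four single-level Haar sub-bands
  (LL/LH/HL/HH, upsampled back to 64×64 by 2×2 replication so they align
  with the mask), and Laplacian-of-Gaussian responses at σ ∈ {1, 2, 3}
  px — each contributing 18 first-order features and 4 angles × 16 GLCM
  descriptors at distance 1: 14 + 8 × (18 + 64) = 670.

Numerical conventions: gray levels are quantized to Q = 32 equal-width
bins over the masked min–max range (a constant region maps to level 0);
GLCM pairs are counted only when both pixels lie in the mask, in both
directions, and normalized to sum 1; logarithms are base 2 with ε = 1e−12
inside every log, so all features are finite on any valid input.  The
first-order smoothness measure is R = 1 − 1/(1 + σ̂²) with σ̂² the
variance of intensities divided by the 8-bit full scale 255; the fixed
scale (rather than per-region min–max) keeps R monotone in the physical
texture amplitude.  GLCM correlation of a zero-variance matrix is defined
as 1.  The LoG channels use an explicitly zero-sum discrete kernel so
constants are annihilated exactly (a truncated analytic kernel leaves a
small DC residual).  The trailing channel token in a GLCM feature name
(e.g. `GLCM_t_45_d_1_Con_orig`) identifies the source channel; the
mapping is recorded in `feature_manifest()`.

Note that under min–max quantization the GLCM is invariant to affine
rescaling of the intensities, so GLCM contrast responds to the *spatial
roughness* (correlation length) of a texture, not to its amplitude;
smoothness R carries the amplitude information.  The test suite checks
both monotonicities on the matching generator ladders.

## The kernelized model

Order of operations (all statistics from training rows only):

1. **Variance threshold** on raw, unstandardized features: a feature is
   removed when its training-set population variance is strictly below
   τ = 0.8 (a variance exactly at the threshold is retained).  Filtering
   must precede standardization — after z-scoring every variance is 1 and
   the threshold would be vacuous.
2. **Standardization** to zero mean, unit variance per retained feature.
3. **Kernel PCA** with the RBF kernel k(xᵢ,xⱼ) = exp(−‖xᵢ−xⱼ‖²/2σ²).
   The kernel width defaults to the median heuristic,
   σ = median pairwise distance / √2, which puts the median off-diagonal
   kernel value at e⁻¹; a fixed σ can be supplied.  The training Gram
   matrix is double-centered, eigendecomposed, and the top m eigenvectors
   scaled by 1/√λ; eigenvalues below 1e−10 of the largest are dropped
   (with a warning) and m reduced.  Out-of-sample rows are projected
   through the centered cross-kernel against the stored training matrix.
   The default dimension is m = 130; optionally m is selected over the
   grid 30…200 (step 10) by inner 3-fold cross-validated AUC, ties broken
   toward the smallest dimension.  AUC rather than accuracy drives every
   selection because the class mix is mildly imbalanced (~61%/39%).
4. **Random forest** on the embedding.  Defaults: 200 trees, unlimited
   depth, √p feature subsampling.  Optional coordinate grid search (one
   full sweep, each parameter optimized with the others frozen, ties keep
   the earlier grid entry) over {100, 200, 500} trees ×
   {3, 5, 10, none} depth × {√p, log₂p, p/3} features.

Cross-validation is stratified 3-fold; per fold the entire chain
(filter → scaler → KPCA → forest) is refitted on the two training parts,
and every subject is scored exactly once out of fold.  Metrics are pooled
over the out-of-fold scores (fold-averaging would be the alternative; the
pooled convention is fixed here and used consistently for the paired
tests).  The positive class is WD, the majority grade.  A leakage probe —
perturbing a held-out row and checking the fold's fitted state
byte-for-byte — is part of the acceptance suite.

## Clinical and combined models

The clinical design matrix has four 0/1 indicators: T3–4 (vs T1–2), N+
(vs N0), stage III–IV (vs I–II), heterogeneous (vs homogeneous)
enhancement.  The clinical model is a random forest of the same
configuration on those four columns (a logistic model would be the
natural alternative; the forest keeps the classifier uniform across
models).  The combined model concatenates the per-fold kernel embedding
(m columns) with the four indicators.  All three models share one
stratified partition per seed, so DeLong (paired AUC) and exact McNemar
(paired correctness) comparisons are valid.

## Evaluation statistics

* AUC is the Mann–Whitney concordance probability, ties counted ½.
* The DeLong test uses placement values: per model, the mean ψ-score of
  each positive against all negatives (and vice versa); the variance of
  the AUC difference combines the two 2×2 placement covariance matrices,
  and z = ΔAUC/SE is referred to the standard normal, two-sided.  A zero
  variance (e.g. identical score vectors) raises a degenerate-comparison
  error; the report-level wrapper records the degeneracy instead.
* McNemar comparisons of paired accuracies use the exact two-sided
  binomial tail on the discordant pairs (the model-comparison p-values in
  this kind of report rarely name their method; the exact test is the
  standard choice for paired proportions and is documented here as a
  reconstruction).
* Chi-square tests are uncorrected Pearson (no continuity correction) —
  the convention that reproduces the printed cohort-table p-values; the
  summary t-test defaults to the pooled Student variant with a Welch
  option.
* Cohen's kappa comes with the large-sample (Fleiss–Cohen–Everitt)
  standard error, a 95% Wald interval, and the conventional bins
  (≤0.20 slight, ≤0.40 fair, ≤0.60 moderate, ≤0.80 substantial,
  ≤1.00 almost perfect).
* Classification metrics at a threshold use forest score ≥ 0.5 by
  default; a Youden-optimal threshold helper is available.  Undefined
  ratios (zero denominators) are reported as NaN, never as 0.

## The phantom generator

Each subject is a 192×192 8-bit image: a smooth horizontal background
gradient (70→105) with mild noise (SD 2), plus an elliptical lesion
(semi-axes 10–24 px, random orientation) whose boundary is perturbed by
low-order radial Fourier modes (orders 2–4, amplitude ≤ 6%) so shape
features vary.  The lesion interior is a stationary Gaussian random field
(filtered white noise) around mean 150 with class-specific parameters:
WD uses correlation length 3 px and SD 6; MD/PD correlation length 1.5 px
and SD 18, plus a Poisson(3) number of hypodense necrosis-like Gaussian
blobs (radius 3–6 px, depth 40–70).  This encodes the qualitative
observation the analysis rests on — WD lesions look smoother, MD/PD
lesions rougher with necrosis.  Background blending is applied only
*outside* the lesion (a soft halo), so in-mask statistics are pure class
texture.  The annotation is the 8-connected ring just outside the lesion
boundary, colored pure red; the original copy carries no red pixels.
Class prevalence defaults to 61.3% WD, the composition of the 206-patient
cohort the analysis was designed around, and the four clinical covariates
are Bernoulli draws whose risk-level logit is shifted by
`clinical_effect` (default 1.0) for MD/PD subjects; 0 makes them
uninformative.

What the phantoms do *not* emulate: Hounsfield-calibrated intensities,
multi-phase contrast, 3-D structure, scanner noise spectra, anatomy, or
inter-observer annotation variability.  Passing tests therefore
demonstrate that the pipeline recovers a planted texture difference
through the full annotation→features→kernel→forest chain with correct
statistics and no leakage — not that it would reach any particular
performance on real CT data.  The default texture contrast is strong by
design (the separability condition for the end-to-end recovery checks);
on default 200-subject cohorts the cross-validated AUC is essentially 1,
and the appended-noise comparison (200 pure-noise columns, SD 0.5, hence
variance 0.25 < τ, removed by the filter) checks the *direction* that
variance-threshold selection is not worse than no selection.

## Problem sizes and seeds

The test suite runs phantom cohorts of 14–60 subjects for module tests
and five 200-subject cohorts for the end-to-end recovery check; the
acceptance script uses three 200-subject cohorts for the
variance-threshold benchmark and one for the three-model comparison.
One global seed fans out to per-stage substreams through
`numpy.random.SeedSequence.spawn`, and each subject renders from its own
child stream, so cohorts are reproducible bit-for-bit and per-subject
images do not depend on cohort size.  Forest randomness is tied to the
same seed; a fixed (config, seed) pair reproduces the full study report
byte-identically.

## Known limitations

* 2-D single-slice analysis only; no DICOM ingestion (8-bit PNG/JPEG
  exports are the input format).
* The 670-feature itemization is this package's documented registry
  (manifest in `feature_manifest()`); the four groups and the total are
  fixed, but other registries of the same size exist.
* The kernel width σ and the forest grids are conventions (median
  heuristic; standard small grids), not estimates from any dataset.
* The minimum annotation area check ("ROI larger than 1 cm²") cannot be
  enforced without pixel spacing and is off by default.
* Inter-observer agreement statistics (kappa) are implemented but the
  phantom generator simulates a single annotator.
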