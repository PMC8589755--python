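# Methods

This note documents the models, conventions and design choices behind
`usradiomics`, in the spirit of the methods documentation of the mature
statistics and imaging packages it imitates.

## Preprocessing

**Grayscale conversion.** Ultrasound captures stored as RGB are collapsed
with the ITU-R 601-2 luma weights, L = R·299/1000 + G·587/1000 + B·114/1000;
already-grayscale input passes through unchanged. Conversion happens before
normalization and before any filtering.

**Normalization.** Whole-image z-scoring, x → ((x − μ)/σ)·100 + 300, makes
images from different scanners and gain settings comparable: the mean maps
to 300 and the ±3σ band spans 0–600 gray units. The 0–600 range is nominal —
values beyond ±3σ are *not* clamped. Clamping was considered and rejected:
the gray-level bins are anchored at the ROI minimum, so the nominal range
never enters the discretization, while clamping would truncate the intensity
tails that the first-order skewness/kurtosis statistics measure. A constant
image (σ = 0) is a hard error naming the offending lesion.

**Discretization.** ROI gray levels use a fixed bin width of 3 gray units
with half-open bins anchored at the ROI minimum:
level(x) = ⌊(x − min_ROI)/w⌋ + 1. Level 1 is therefore always occupied, the
level count adapts to the ROI dynamic range, and adding a constant to the
ROI leaves levels unchanged. Filtered images are re-discretized with the
same bin width — uniform treatment across the image bank.

## The filtered image bank

Features are extracted from the original normalized image and nine filtered
versions.

**Laplacian of Gaussian** at σ = 1, 2, 3, 4, 5 px, with reflective
boundaries. The implementation is separable (G″ₓ∗G_y + Gₓ∗G″_y) with
truncated kernels explicitly corrected to sum to 1 (smoothing) and 0
(second derivative), so the response to constant and linear images is zero
to machine precision — the raw truncated-kernel operator leaves a ~10⁻³
residue that would contaminate low-contrast ROIs. Bright blobs of matching
scale give negative center responses.

**Wavelet subbands.** A one-level separable 2D stationary (undecimated)
wavelet transform with the Coiflet-1 basis (configurable) yields LL/LH/HL/HH
subbands at the original resolution, so the untouched lesion mask applies
directly — no mask-resampling ambiguity. The normalized form of the
transform is used: it conserves energy for an orthogonal basis and inverts
exactly. Odd image sizes are reflect-padded to even and cropped back.
Subband tags are ⟨row-filter⟩⟨column-filter⟩; single-letter subband labels
seen in some feature exports map via `filters.WAVELET_ALIASES` (H → HH,
L → LL).

## Features (874 with defaults)

Per lesion: 4 shape features from the mask, plus 18 first-order + 69
texture features for each of the 10 images (4 + 10 × 87 = 874). Keys are
`<provenance>_<family>_<name>`. The manifest is derived from the
configuration, not hard-coded, because published feature counts in this
literature depend on unrecoverable per-filter settings; the package reports
its own manifest size instead.

**Shape (dimensionless).** Perimeter-surface ratio P/A, sphericity
2√(πA)/P, spherical disproportion (its reciprocal), and elongation
√(λ_minor/λ_major) from the eigenvalues of the foreground-coordinate
covariance. Only zoom/depth-invariant descriptors are exposed (P/A is
dimensionful 1/length but belongs to the standard set). The perimeter is a
4-direction Crofton estimate: it is asymptotically unbiased for smooth
convex boundaries (a rasterized disk of radius 50 gives sphericity 1.002),
where pixel-edge counting is ~27% biased and marching-squares contour
length ~5%.

**Texture matrices.** All four families share these conventions: 2D angles
0°/45°/90°/135° at distance 1; symmetric GLCM; per-angle GLCM/GLRLM feature
values averaged over angles; GLSZM zones 8-connected and orientation-free;
GLDM dependence = number of 8-neighbors inside the mask with level
difference ≤ α = 0, with feature formulas using the dependence size
d + 1 (center included) so every pixel contributes once and no division by
zero arises. Pixels outside the mask never contribute: pairs straddling the
boundary are dropped and runs break at the boundary. The GLCM family
comprises the standard 24-feature set minus sum average (a known redundancy
with joint average under symmetry).

**Degenerate ROIs.** A single-level ROI makes correlation-type GLCM
features 0/0; Correlation and MCC are defined as 1 (a one-level texture is
perfectly autocorrelated), Imc1/Imc2 as 0, and zero-variance first-order
skewness/kurtosis as 0. These conventions keep NaNs out of downstream
selection.

**Validation.** Every texture and first-order feature is checked against an
independent pure-Python enumeration oracle (loops and dicts, no shared
code) on 100 random 8×8 ROIs with ≤ 6 levels, to 10⁻⁹.

## Synthetic cohort generator

The generator fabricates the two sonographic phenotypes the classifier must
separate; its defaults define the package's study conditions.

**Geometry.** The lesion boundary is star-convex:
r(φ) = ellipse(a, b) · (1 + irregularity term), where the base ellipse has
area π·R² (R = `mean_radius`, default 15–16 px in a 128×128 image) and axis
ratio `elongation_ratio`, and the irregularity term is a random Fourier
series of orders 2–8 scaled to RMS amplitude `boundary_irregularity`·R.
One amplitude knob thus controls margin irregularity. Orientation is
random; lesions exceeding the image raise an error.

**Echotexture.** Interior intensities are a spatially correlated Gaussian
field (SD `heterogeneity_sd`, Gaussian-kernel correlation length
`correlation_length`) around `lesion_mean_intensity`; the background is an
analogous field around 110 gray units. The whole image is multiplied by
i.i.d. unit-mean gamma speckle with shape 60 (≈ 13% coefficient of
variation — a standard approximation of fully developed B-mode speckle;
only the unit-mean/variance contract is asserted). Malignant-like lesions
optionally cast a posterior acoustic shadow (smooth 45% darkening below the
lesion).

**Class defaults** (chosen once as plausible sonographic phenotypes):
benign — oval (axis ratio 0.55), smooth margin (irregularity 0.04),
homogeneous interior (SD 5); malignant — rounder (0.80), irregular margin
(0.22), heterogeneous (SD 16), darker (55 vs 70), shadowing. Per-lesion
diversity comes from seeded jitter of radius, intensity and axis ratio.
With these defaults the classes separate on GLCM contrast with a
standardized effect size above 1 (a generator contract under test), and
using the same spec for both labels yields a null cohort on which the
cross-validated AUC stays near 0.5.

**Simulated annotators.** A reader's mask re-thresholds the reference
mask's signed distance against a smooth unit-SD noise surface scaled by
`magnitude` × equivalent radius (boundary-normal Gaussian displacement),
plus an occasional one-pixel morphological erosion/dilation. Magnitude 0 is
the identity; 0.05 (the default) gives Dice ≈ 0.93 and produces ICC values
on both sides of the 0.75 threshold, so the stability filter has real work
to do. An emptied mask is retried and then a hard error.

**What the generator does not emulate:** attenuation with depth, refraction
and reverberation artifacts, anisotropic point-spread functions, calcifications,
posterior enhancement of cysts, or operator-dependent framing. Passing the
end-to-end checks therefore demonstrates that the pipeline recovers planted
class structure under speckle-like noise and annotator variability — not
clinical-grade performance on real ultrasound.

## Stability filtering

ICC(2,1) — two-way random effects, single rater, absolute agreement — is
computed per feature from the n×k ratings matrix via the ANOVA mean squares
(vectorized across features):
ICC = (MS_R − MS_E)/(MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)). This exact
variant is hard-selected; other ICC forms are out of scope. An all-equal
matrix returns 1 by convention. Features with ICC ≥ 0.75 (inclusive) across
the designated reader-subset lesions (default: 30 training lesions, 3
readers) are retained. The implementation is verified against an
ANOVA-by-summation oracle to 10⁻¹⁰ and against `pingouin.intraclass_corr`.

## Selection cascade

Stage order is fixed: ICC → MinMax scale → variance → correlation → SMOTE →
RFECV. All parameters are learned from training rows only; the external
test set is transformed with frozen parameters and never refit (a hard test
permutes/replaces test rows and asserts bit-identical decisions).

* **MinMax** maps each training column to [0, 1]; test values may fall
  outside and are not clipped; constant columns map to 0 and fall to the
  variance filter.
* **Variance filter** drops population variance ≤ 0.01 (inclusive),
  computed after scaling.
* **Correlation filter** greedily removes features until no pair has
  |Pearson r| ≥ 0.8. Tie-break (the literature is silent): among features
  in violating pairs, drop the one with the largest mean absolute
  correlation against the remaining features — the most redundant goes
  first — with ties broken by manifest order (later feature dropped).
  Deterministic by construction.
* **SMOTE** (implemented in-package): synthetic = x + u·(x_nn − x),
  u ~ U(0,1), x a minority row, x_nn one of its k = 5 nearest minority
  neighbors by Euclidean distance on the scaled features, repeated until
  the classes are exactly balanced. It is applied once to the full training
  set, after the filters and before RFECV. The methodological caveat is
  acknowledged: balancing before cross-validation lets synthetic neighbors
  of validation rows into training folds, so CV estimates on balanced data
  are optimistic; a fold-internal mode would avoid this but is not the
  workflow this package reproduces.
* **RFECV**: stratified 10-fold CV recursive elimination (one feature per
  step, ranked by |logistic-regression coefficient|, LBFGS solver),
  accuracy scoring; the smallest feature count achieving the maximal mean
  CV score wins. Folds with a single class are a hard error.

All stochastic stages (SMOTE, fold shuffling) draw seeds derived from one
master seed; the derivation (SeedSequence over stage ids, 31-bit) is
recorded in the run manifest.

## Classifier

A random forest with a fixed reference configuration: 400 trees, Gini
impurity, bootstrap, no class weights, unlimited depth/leaves, 5 candidate
features per split (capped at the feature count), min samples split/leaf
2/1. Assessment is stratified 5-fold CV (per-fold accuracy, PPV,
sensitivity, specificity, AUC with mean ± SD) followed by a final fit on
the whole training set. The class call threshold is fixed at probability
0.5 for the malignant (positive) class. A seeded random-search utility over
a logged hyperparameter space is provided for re-tuning, but the default
configuration is the reference; no attempt is made to reproduce an
unspecified search trajectory.

## Evaluation statistics

* **Ratio metrics** (accuracy, sensitivity, specificity, PPV, NPV) are
  percentages with exact Clopper–Pearson 95% binomial CIs (Wilson by flag);
  zero-denominator metrics are reported as undefined rather than NaN.
* **NIR test**: NIR = majority-class prevalence; p = P[X ≥ correct],
  X ~ Binomial(total, NIR), one-sided exact.
* **McNemar**: exact two-sided binomial on the discordant counts (b, b+c)
  when b + c < 25, else χ² with continuity correction ((|b−c|−1)²/(b+c));
  b + c = 0 returns p = 1 with a no-discordance flag.
* **AUC** by midranks (equals the pairwise concordance probability,
  verified against a brute-force counter), with a DeLong CI; the CI
  degenerates to [0, 1] when either class has fewer than two cases.
* **Brier score** and an equal-width-bin **calibration table** (empty bins
  omitted) complete the probability-quality assessment.

## Problem sizes used in the automated checks

The end-to-end checks run on a 135-lesion training cohort (91 benign / 44
malignant, three readers on 30 lesions) with a 66-lesion test cohort
(21 / 45) — the class-imbalance structure the SMOTE stage is designed for
(44 vs 91 → exactly 47 synthetic rows) — and a 200-lesion null cohort.
Unit tests use smaller cohorts and reduced filter banks where the property
under test does not depend on scale.

## Known limitations

* The feature definitions follow the common radiomics formulations but 2D
  texture conventions vary between toolkits (angle sets, degenerate-value
  conventions, normalization order); absolute feature values are therefore
  comparable within this package, not across toolkits.
* SMOTE-before-CV optimism (above) is reproduced deliberately.
* The synthetic generator supports validation, not benchmarking; reported
  synthetic AUCs are near-ceiling by design of the strong-effect phenotypes.
* DICOM support is read-only, single-frame, pixel data only.
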