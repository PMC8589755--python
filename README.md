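# usradiomics

A radiomics + machine-learning pipeline for discriminating **benign from
malignant breast lesions on 2D B-mode ultrasound images**, built for
researchers who want a tested, leakage-guarded, end-to-end reference
implementation of the classic "hand-crafted features + random forest"
workflow — together with a synthetic lesion-image generator so the whole
pipeline can be exercised and validated without any patient data.

## What it does

Given lesion images with binary region-of-interest (ROI) masks and
benign/malignant labels, the pipeline:

1. **Preprocesses** each image: ITU-R 601-2 luma conversion
   (L = 0.299 R + 0.587 G + 0.114 B), whole-image z-normalization mapped to a
   nominal 0–600 range (scale 100, shift 300), and fixed-bin-width
   discretization of ROI gray levels (width 3).
2. **Extracts 874 features** per lesion: 4 dimensionless 2D shape features,
   plus 18 first-order and 69 texture features — gray-level co-occurrence
   (GLCM, 23), run-length (GLRLM, 16), size-zone (GLSZM, 16) and dependence
   (GLDM, 14) matrices — from the original image and nine filtered versions
   (Laplacian-of-Gaussian at σ = 1…5 px and the four subbands of a one-level
   stationary coif1 wavelet transform).
3. **Filters for inter-reader stability** with the two-way random-effects,
   single-rater, absolute-agreement intraclass correlation,

   ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)),

   keeping features with ICC ≥ 0.75 across annotators.
4. **Selects features** with a train-only cascade: MinMax scaling to [0, 1],
   variance pruning (σ² ≤ 0.01 dropped), pairwise-correlation pruning
   (|r| ≥ 0.8), SMOTE class balancing (k = 5 nearest minority neighbors),
   and stratified 10-fold recursive feature elimination (RFECV) with a
   logistic-regression estimator.
5. **Classifies** with a 400-tree Gini random forest (bootstrap, unlimited
   depth, 5 features per split) assessed by stratified 5-fold CV and a final
   fit, and **evaluates** with accuracy/sensitivity/specificity/PPV/NPV plus
   exact binomial 95% CIs, the exact binomial no-information-rate (NIR)
   test, AUC with a DeLong CI, the Brier score, a calibration curve, and
   McNemar's test for paired reader-vs-model comparisons.

Every texture feature is validated against an independent brute-force
enumeration oracle to 1e−9, and every data-driven selection decision is
fitted on training rows only (enforced by tests).

## Worked example

Confusion-table metrics with exact binomial CIs and the NIR test, here for a
66-lesion test set with 42 true positives, 3 false negatives, 12 true
negatives and 9 false positives:

```python
from usradiomics import ConfusionTable, confusion_metrics, nir_test

ct = ConfusionTable(tp=42, fn=3, tn=12, fp=9)
report = confusion_metrics(ct)
for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
    m = getattr(report, name)
    print(f"{name:12s} {m.percent:5.1f}%  (95% CI {m.ci_low:.1f}-{m.ci_high:.1f})")
nir, p = nir_test(ct)
print(f"NIR          {100*nir:5.1f}%  p vs NIR = {p:.4f}")
```

prints

```
accuracy      81.8%  (95% CI 70.4-90.2)
sensitivity   93.3%  (95% CI 81.7-98.6)
specificity   57.1%  (95% CI 34.0-78.2)
ppv           82.4%  (95% CI 69.1-91.6)
npv           80.0%  (95% CI 51.9-95.7)
NIR           68.2%  p vs NIR = 0.0098
```

i.e. the classifier calls 93% of malignant lesions correctly, is right 82%
of the time overall, and beats always-guess-the-majority-class (68.2%)
with p ≈ 0.01.

## Command-line pipeline

```bash
usradiomics run --seed 7 --out runs/demo        # simulate → … → evaluate
usradiomics simulate --seed 7 --out runs/demo   # or stage by stage
usradiomics extract  --seed 7 --out runs/demo
usradiomics select   --seed 7 --out runs/demo
usradiomics train    --seed 7 --out runs/demo
usradiomics evaluate --seed 7 --out runs/demo
```

Each stage writes its artifacts (PNG images/masks, CSV feature tables, JSON
reports) atomically into the run directory along with a `run_manifest.json`
recording the config hash, derived seeds and stage-by-stage feature counts
(for a small demo cohort: 874 extracted → 707 ICC-stable → 80 after
correlation pruning → 5 RFECV-selected); one master seed reproduces a run
byte-for-byte. A YAML config (`--config`) can override any block; see
`usradiomics.pipeline.RunConfig` for the schema.

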