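# dcipred

Prediction of **delayed cerebral ischemia (DCI)** after aneurysmal
subarachnoid hemorrhage from bedside vital-sign time series, using masked
convolutional dictionary learning for feature extraction, minimal-redundancy
maximal-relevance (mRMR) feature selection, and PLS / class-weighted SVM
classifiers under a derivation/validation protocol.

DCI — secondary ischemic injury from cerebral vasospasm, typically between
post-bleed days 3 and 14 — affects roughly a third of SAH patients. The
clinical standard for risk stratification is the admission CT blood burden
(modified Fisher scale), which is static and imprecise for individuals. This
package implements an agnostic alternative: learn short, shift-invariant
temporal kernels directly from the first four days of routine monitoring
data (heart rate, respiratory rate, systolic/diastolic blood pressure,
SpO2), and use each kernel's maximal match against a patient's record as a
candidate predictor.

## The model

Each channel is downsampled by window means to periods
ds ∈ {1, 5, 10, 20, 60, 120, 240} min. At each scale, a dictionary
D = {d₁,…,d_K} of unit-norm kernels of length KL ∈ {2, 5, 8, 10, 20, 40}
and sparse activation maps Γ are learned by

```
min_{D,Γ}  ‖W(X − Σₖ dₖ ∗ Γₖ)‖² + λ Σₖ ‖Γₖ‖₁ ,   ‖dₖ‖₂ ≤ 1
```

where `∗` is convolution and `W` a binary mask that zeroes the residual over
missing data (mask decoupling). Both subproblems are solved by ADMM in the
frequency domain. With K = 20 kernels per (variable, ds, KL) cell, the full
grid yields 5 × 7 × 6 × 20 = **4,200 candidate kernel features**; each
feature is `f = max(X ∗ γ)`, the maximal valid cross-correlation of a kernel
with the patient's censored, z-scored series, evaluated only on contiguous
observed runs at least twice the kernel length.

Features (kernel + baseline: age, sex, dichotomized Hunt–Hess and modified
Fisher, GCS) are ranked by greedy mRMR (MID or MIQ criterion, plug-in mutual
information on quantile-binned values), and scored by PLS regression or
class-weighted linear/RBF SVMs. Evaluation follows the cohort protocol: an
80/20 stratified split; internal validation as the median AUC over 100
stratified 12.5% hold-outs of the derivation set (every fitted step refit per
run); a single validation AUC with a Hanley–McNeil 95% CI; correlated-ROC
z-tests for model comparison.

No patient data is distributed; a synthetic cohort generator
(`dcipred.synthetic`) reproduces the statistical structure the method
assumes — class-specific temporal motifs at multiple scales, missing
segments, ~30% outcome prevalence, baseline covariate effects — so the whole
pipeline is testable end to end.

## Worked example

`examples/05_full_protocol.py` runs the full protocol on the planted-signal
(`easy`) and signal-free (`null`) presets with a reduced learning grid
(HR+RR, ds {1,5} min, KL {5,10}, K=5):

```
 easy: median hold-out AUC 1.000 | validation AUC 1.000 (95% CI 1.00-1.00) | n=160+40
 null: median hold-out AUC 0.604 | validation AUC 0.464 (95% CI 0.28-0.65) | n=160+40
```

On the `easy` preset the positive class carries a distinct fast biphasic
motif in HR/RR at within-event SNR 10; the learned kernels match it, the
mRMR-selected features separate the classes, and hold-out discrimination is
essentially perfect. On `null` (no motifs, no covariate effects) the same
pipeline stays at chance — any single finite cohort fluctuates around 0.5,
which is why the calibration experiment below averages over replicate
cohorts. The other examples each demonstrate one capability (simulation and
I/O, kernel recovery, featurization, mRMR ranking, correlated ROC
comparison) and print what the numbers mean.

A thin CLI wraps the same pipeline:

```sh
dcipred simulate --preset tiny --seed 0 ts.csv baseline.csv
dcipred run-all --preset tiny --seed 0 --cv-runs 10 --outdir runs/demo
```

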