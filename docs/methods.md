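# Methods

## Problem and model

The package predicts delayed cerebral ischemia (DCI) after aneurysmal
subarachnoid hemorrhage from the first four days of routine bedside
monitoring (HR, RR, SBP, DBP, SpO2 on a regular grid, nominally 0.2 Hz) plus
admission covariates (age, sex, Hunt–Hess, modified Fisher, GCS). The
premise is that short, recurring temporal motifs in vital signs carry
prognostic information that static admission grades do not, and that these
motifs can be discovered without hypotheses by convolutional (shift-
invariant) dictionary learning.

For a series X with binary observation mask W, the model is

    min over D, Γ of  ‖W(X − Σ_k d_k ∗ Γ_k)‖² + λ Σ_k ‖Γ_k‖₁,  ‖d_k‖₂ ≤ 1.

Missing data enters only through W (mask decoupling): masked samples
contribute no residual, so gaps neither distort the learned kernels nor
require imputation at the signal level. Kernels are learned per
(variable, downsampling period, kernel length) cell so that dynamics at
time scales from minutes to hours are all represented; downsampling is by
non-overlapping window means anchored at rupture time, which also absorbs
isolated artifacts.

### Solvers

Both subproblems use ADMM with the masked residual as a separate split
block.

*Sparse coding* (D fixed): splitting y0 = X − DΓ, y1 = Γ. The Γ-update is a
per-frequency linear solve done in O(K) by Sherman–Morrison; the y0-update
is the closed-form prox of ‖W·‖² (masked samples take the residual freely);
the y1-update is soft thresholding. Convolutions are circular on a support
zero-padded by one kernel length with W = 0 on the pad, so wrap-around never
touches the objective. Verified against a generic lasso solver on the
equivalent masked Toeplitz design (objective agreement ~1e-14 relative on
small instances; the acceptance check requires 1e-4).

*Dictionary update* (Γ fixed): same masked-residual splitting plus a
constraint block g = d projected onto {support ≤ KL, ‖d‖ ≤ 1}; the d-update
solves K×K per-frequency normal equations batched over frequencies. ADMM is
not monotone, so the update is accepted only if it does not increase the
masked fidelity at fixed Γ; otherwise the previous atoms are kept. Together
with a best-iterate guard in sparse coding this makes the outer objective
trace non-increasing by construction (the property tests assert it). Atoms
with zero total activation are re-seeded from the worst-reconstructed
observed window and flagged.

At the end of learning, atoms are scaled to exact unit norm with activations
rescaled inversely (reconstruction unchanged, ℓ1 can only shrink) and sorted
by total activation energy for bit-reproducibility. All randomness flows
from one seed; identical inputs and seed give bit-identical dictionaries.

### Features

A kernel feature is f = max(X ∗ γ): the signed maximum of the valid
cross-correlation over every contiguous observed run at least twice the
kernel length (runs shorter than that yield nothing; a patient with no
qualifying run gets a missing value). `∗` is implemented as correlation —
the feature is a template match — with a flip switch for strict convolution.
Features are computed on the same per-variable z-scored scale the
dictionaries were learned on (statistics from the derivation cohort only),
so kernels encode dynamics rather than offsets. The maximum is signed, not
absolute: kernels for inverted motifs must be learned as such.

With the full grid (5 variables × 7 periods × 6 kernel lengths × 20
kernels) the candidate set enumerates 4,200 columns. Under a strict 4-day
window, cells where twice the kernel length exceeds the number of samples
(KL 20 and 40 at 240-min sampling; KL 40 at 120-min) can never produce a
qualifying run: the columns exist and are reported missing. The grid
enumeration experiment therefore uses long-span records; the clinical
protocol keeps the 4-day censoring and lets imputation absorb the
structurally missing cells.

### Selection and classifiers

mRMR ranks features greedily: the first pick maximizes relevance I(x, h);
each later pick maximizes relevance minus (MID) or divided by (MIQ, with an
ε = 1e-12 guard) the mean mutual information with the already-selected set.
MI is the plug-in estimate in nats on quantile-binned values (10 bins; ties
to the lower bin; missing is its own category; already-discrete columns pass
through). Default criterion MID, default k = 80 at full grid, k = 20 on the
reduced test grid.

Classifiers: PLS regression of the 0/1 label on the first c = 3 latent
components (score = predicted response); linear and RBF SVMs with class
weights inversely proportional to class frequency (C = 1; RBF width by the
median heuristic on training distances). Evaluation: midrank Mann–Whitney
AUC; Hanley–McNeil SE for CIs; correlated-ROC z-test with r estimated as
the average of the within-positive and within-negative Pearson correlations
of the two score vectors (a close approximation of the published lookup
table; a DeLong variant is available).

### Protocol and leakage control

80/20 stratified split (derivation/validation); dictionaries are learned on
the derivation split only. Internal validation is the median AUC over 100
stratified 12.5% hold-outs; imputation (per-column training median),
standardization, mRMR and the classifier are refit inside every run on the
87.5% only. The order of operations for selection is deliberately the
leak-free reading: selection inside each run, never on the full derivation
set. The validation split is touched exactly once.

## Synthetic cohorts

The generator reproduces the structure the method assumes and nothing more:
AR(1) baselines at per-variable physiologic levels, white noise, masked
gaps (Poisson starts, exponential lengths), class-conditional motifs planted
at random positions, baseline covariates tied to the label through a
logistic model calibrated to ~30% prevalence, and exact counts of
early-event and all-missing records for the exclusion arithmetic
(562 → −8 → −66 → 488 in the cohort-structure preset). It does *not* model
circadian rhythm, treatment response, cross-channel coupling or realistic
artifact distributions — so passing tests demonstrate the pipeline's
statistical machinery, not clinical performance on real monitoring data.

Definitions chosen where the design was open:

- **SNR** is within-event signal power over noise power: for a unit-norm
  kernel of length r, noise SD = amplitude/√(snr·r). (An amplitude-to-noise
  reading would make "SNR 10" a per-sample ratio near 1, which is not what
  anyone means by it.)
- The default class motifs are a fast two-cycle oscillation (positive class)
  and a slow bump (negative class); their maximal shift-invariant
  cross-correlation is 0.33, so a kernel matched to one cannot fire on the
  other. Early shapes with 0.8 mutual correlation made the classes
  indistinguishable by any template feature, which defeats the generator's
  purpose of providing class-specific motifs.
- The cohort-structure preset uses a 5-minute grid: the exclusion
  counts it exists for do not depend on sampling rate, and a 0.2 Hz, 562
  patient, 5-channel cohort would occupy ~1.5 GB for no informational gain.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lam_frac`) | 0.1 × λ_max | sparsity weight as a fraction of the smallest λ that zeroes all coefficients at init |
| ρ | 10λ, adaptive | ADMM penalty, residual-balanced every 10 iterations |
| K | 20 | kernels per grid cell |
| kernel lengths | 2, 5, 8, 10, 20, 40 samples | motif durations per downsampling period |
| ds periods | 1–240 min | time scales of the multiscale bank |
| outer / ADMM iterations | 15 / 100 | alternations and inner solver effort |
| `max_series` | 50 | series subsampled per dictionary cell |
| mRMR k / criterion | 80 / MID | selected features at full grid |
| PLS components / SVM C | 3 / 1 | classifier capacity |

λ_frac = 0.1 reconstructs well but under-sparsifies for *motif discovery*;
the recovery experiments use 0.3–0.5, where planted kernels at SNR 10 are
recovered (shift-invariant correlation > 0.9) in ≥ 90% of seeded runs. The
reduced experiment grid (HR+RR, ds {1,5} min, KL {5,10}, K=5, mRMR k=20)
keeps an end-to-end run in minutes while exercising every code path;
iteration budgets there (8 outer / 40 ADMM alternations, 24 series per
cell) are the package's chosen desk-scale operating point.

## Numerical and degenerate-input choices

- Exclusion boundary "before post-bleed day 3" is strict: an event at
  exactly 3.0 is retained.
- Partially observed downsampling windows average whatever is observed (no
  minimum-coverage threshold); empty windows are masked.
- Quantile binning sends ties to the lower bin; a column with ≤ bins
  distinct values passes through unbinned.
- Stratified splits allocate per class by rounding, clamped so neither side
  of a split is empty for either class; single-class hold-outs are redrawn
  (≤ 10 times) before erroring.
- Zero-variance or all-missing feature columns are dropped at
  standardization and reported.
- Identical score vectors short-circuit the correlated-ROC test to
  (z=0, p=1) rather than dividing 0 by 0.
- Sex is encoded female = 1; GCS enters continuously (only Hunt–Hess and
  modified Fisher are dichotomized, at ≥4 and ≥3).

## Calibration of the null check

A single finite null cohort (n = 200) carries chance feature–label
correlation: across replicate cohorts the median hold-out AUC of the full
pipeline fluctuates around 0.5 with SD ≈ 0.09, with or without feature
selection — this is sampling variance, not leakage. The null-calibration
experiment therefore reports the mean of per-cohort medians over four
replicate cohorts (replicate seeds derived from the input seed), an
estimator with SD ≈ 0.045 that lands in [0.40, 0.60] with ~97% probability
under the null. Dictionary solver effort is reduced for these replicates,
since under the null the features are label-independent regardless of
solver convergence.

## Known limitations

- The ADMM sparse coder targets moderate accuracy; tight tolerances (1e-8
  relative) need a few thousand iterations on small instances.
- Kernel features use only the maximum activation; count- or energy-based
  summaries of Γ are not implemented.
- The correlated-ROC r is an approximation of the published table (see
  above); for publication-grade comparisons use the DeLong option.
- Dictionary learning is non-convex: different seeds give different local
  optima. Determinism is guaranteed per seed, global optimality is not.
- The CLI covers the pipeline stages but not bank introspection; use the
  library API for anything beyond the standard protocol.
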