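# Methods

`copdscreen` implements a complete respiratory-sound screening pipeline for
the binary COPD-vs-healthy task: synthetic cohort generation, preprocessing,
log-Mel feature extraction, L1-sparse spectrogram masking, a compact
SE-Conv1D classifier with attentive statistics pooling, patient-wise
cross-validated evaluation, SNR robustness analysis and Grad-CAM
interpretability. This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Synthetic cohorts

Real auscultation corpora for this task are large downloads with restrictive
licensing; the package therefore ships a generative model of the *statistical
structure* the pipeline must handle, used both as the test fixture and as the
default data source.

Per recording, a respiratory-cycle amplitude envelope (two raised-cosine
lobes per period; inspiration/expiration duration ratio `ie_ratio`, default
0.6, period ~4 s with ±10% jitter) modulates band-limited white breath noise.
Class signatures:

- **Healthy** — breath noise band 100–1200 Hz, no adventitious events.
- **COPD** — breath noise band-limited to 100–800 Hz (attenuated upper band),
  plus sustained wheezes (sinusoids with ≤2% vibrato, 150–550 Hz,
  ≥250 ms, probability 0.85 per expiration, expiration-gated) and crackle
  transients (damped oscillations ≤20 ms, Poisson rate 1.5 per cycle). Every
  COPD recording is guaranteed at least one event.

Durations are Normal(20 s, 2 s) for healthy and right-skewed lognormal
centered near 20 s for COPD, mirroring the duration structure of clinical
recordings with longer COPD outliers. The default patient imbalance is 64:26
(COPD:healthy), scaled proportionally at desk scale (e.g. 14:6), with more
recordings per COPD patient (2–4) than healthy patient (1–2). A −30 dB white
noise floor is added; amplitudes are peak-normalized to 0.9 and clipped to
[−1, 1].

Reproducibility: the cohort seed is expanded via `numpy` `SeedSequence`
lists (`[seed, patient, recording]`) into one independent substream per
recording, so `(spec, seed)` fixes every sample bit-exactly.

**What this generator does not emulate:** physiological airway acoustics,
recording-device and body-position variability, inter-patient acoustic
heterogeneity, ambiguous borderline cases. The classes are separable *by
construction* (a one-dimensional band-energy statistic already separates
them), so passing end-to-end tests demonstrates that the pipeline recovers a
known signal without leakage — not clinical performance.

## Preprocessing and splits

Recordings are collapsed to mono, resampled to 16 kHz
(`scipy.signal.resample_poly`), and tiled into non-overlapping 5 s clips;
the trailing remainder is dropped, not padded (padding would distort energy
statistics). Clips are amplitude-normalized to zero mean / peak 1 before
feature extraction, which keeps the SNR bookkeeping of the robustness sweep
clean.

All partitioning is at the patient level and class-stratified.
Train/val/test uses largest-remainder rounding of the 70/15/15 ratios within
each class (total and deterministic for tiny cohorts); k-fold CV deals
shuffled patients round-robin per class so every fold's class mix is within
one patient of the global mix, and every patient is validated exactly once.
A no-leakage assertion (no patient in two partitions) runs on every split.
Minority oversampling duplicates *clips* (the training unit), cycling
deterministically until class counts are equal, and is applied to the
training split only.

## Features

80-bin log-Mel spectrograms: 25 ms Hann window, 10 ms hop, centered frames
(frame count `1 + floor(n/hop)`, i.e. 501 for a 5 s clip), 512-point FFT,
HTK-mel triangular filters on 0–8000 Hz, natural log of mel power plus a
1e−6 floor (prevents −∞ on silence). Only the 80-bin count is externally
fixed; the rest are the standard speech-processing defaults this
architecture family assumes.

Noise injection is SNR-controlled: for target SNR (dB),
`P_noise = P_signal / 10^(SNR/10)` with `P_signal` the mean squared input,
and `x̃ = x + n`, `n ~ N(0, P_noise)`. The relation is exact analytically and
holds within 0.2 dB empirically at 10⁶ samples. The robustness sweep injects
in the log-Mel domain (the representation the model consumes); a
waveform-domain mode is available since the additive-noise formulation is a
time-domain statement.

SpecAugment masks 1 frequency band (≤10 bins) and 1 time span (≤20 frames)
per training clip with the spectrogram mean — deliberately conservative so
augmentation cannot erase the minority class's narrowband evidence. Inputs
to the network are per-clip standardized (zero mean, unit variance over the
clip).

## Lasso spectrogram masking

Standardized per-clip spectrograms are aligned to a fixed 80×501 grid
(shorter matrices right-padded with the clip mean, longer ones
center-cropped), flattened row-major (frequency-major), and column-wise
standardized (constant columns flagged, scale 1). The 0/1 class code is
regressed with the lasso objective
`(1/2n)‖y − Xβ‖² + λ‖β‖₁` (squared error — the selection step is a
regression-based screen, not the classifier). The response is centered
before fitting, which is equivalent to an intercept at the class prevalence
and leaves the coefficients unchanged (standardized columns have zero mean);
without it the CV would compare candidate models against a mis-specified
baseline that no coefficient can absorb. λ is chosen by
cross-validated MSE over a log-spaced grid from `λ_max = max|Xᵀy|/n` down to
10⁻³ λ_max (100 points at full scale, 20–30 at desk scale); the internal CV
is grouped by patient so the no-leakage rule extends into the selector.
Cells with nonzero refit coefficients are kept; the mask is reshaped to
80×501 and applied by setting dropped cells to the per-clip mean (zero is
not neutral on a log-energy scale; the clip mean is, after per-clip
standardization). The mask is fitted per training split (per fold in CV) and
reapplied unchanged to held-out data. If the CV-selected solution is fully
shrunk, the selector degrades to a pass-through mask rather than blanking
the input.

The solver is scikit-learn's coordinate descent; its correctness is
cross-checked in the tests against the orthonormal-design closed form
`β̂_j = sign(β_j^OLS)·max(|β_j^OLS| − λ, 0)` (agreement to 1e−6) and a
planted-support recovery experiment (3 informative of 200 features, n=150,
σ=0.1).

## Classifier

A compact ECAPA-style time-delay network over the 80 mel bands, implemented
on a small vectorized reverse-mode autodiff engine (`copdscreen.nn`) written
on numpy — forward and backward passes, AdamW, and gradient capture at
intermediate feature maps (needed for Grad-CAM) are all first-class.

Default stack (`PlainConvSE`): optional per-band frequency gate →
Conv1D(k=5, 80→C)+BN+ReLU → SE → Conv1D(k=3)+BN+ReLU → SE →
Conv1D(k=3)+BN+ReLU → SE → pooling → dropout(0.2) → linear embedding →
linear 2-class head. Full-size capacity is C=1024 channels with a 192-d
embedding; the desk preset (C=64, 64-d) preserves every contract at test
scale. An opt-in `SERes2` variant replaces the second and third stages with
multi-scale Res2 residual blocks (4 scales, dilations 2 and 3) plus a 1×1
aggregation convolution, for the multi-scale flavor of the architecture
family; the plain stack is the default because it is the fully specified
variant.

- **Attentive statistics pooling (ASP, default):** a 128-unit tanh
  bottleneck scores each frame; softmax over time yields weights α_t ≥ 0,
  Σα_t = 1; the pooled vector concatenates the weighted mean
  μ = Σ α_t h_t and the *biased* weighted standard deviation
  σ = sqrt(Σ α_t (h_t − μ)²), exactly as the pooling statistic is defined.
  `GlobalAvg` pooling is the "without ASP" ablation and is a pure config
  swap.
- **SE gating:** squeeze (temporal mean) → bottleneck (reduction 16, the
  standard value) → sigmoid gate in (0,1), applied per channel;
  `se_enabled=False` is the "without SE" ablation.
- **Frequency gate:** per-band multiplicative gate `2·sigmoid(b)` with b=0
  at init, so the gate starts as an exact identity and can both attenuate
  and amplify a band. (A plain sigmoid gate cannot start at identity; the
  factor-2 parameterization was chosen for that reason.)
- **Head:** two logits with softmax cross-entropy — decision-equivalent to a
  single sigmoid unit for a binary task, and it matches the tabulated layer
  shapes.

Numerical choices: Kaiming-normal init from a per-model seed (two builds
with one seed are parameter-identical); BatchNorm running statistics are
seeded from the first training batch and then updated with momentum 0.1 —
with only ~10 optimizer steps per desk-scale epoch, an arbitrary (0, 1) init
would dominate eval-mode statistics for several epochs and systematically
miscalibrate early-epoch validation; σ in ASP adds 1e−10 under the square
root; float32 throughout the network.

## Training and evaluation

Fixed recipe: AdamW, lr 5e−4, weight decay 0, batch 32, ≤50 epochs
(≤10 at desk scale), early stopping with patience 3 on validation F1, and
restoration of the best-validation-F1 epoch's parameters. Epochs where the
selection metric is undefined (no positive predictions yet) count neither as
improvement nor toward patience — stopping on them would return a degenerate
single-class model. NaN loss aborts with diagnostics.

Imbalance handling: `oversample` (default; resampling upstream, unweighted
loss), `class_weight` (inverse-frequency weights normalized to mean 1), or
`none`.

Metrics are confusion-matrix-derived with COPD positive: accuracy,
precision, recall (COPD sensitivity), specificity, F1, plus ROC-AUC from the
positive-class score (rank-statistic formulation via scikit-learn).
Undefined ratios are reported as NaN with a warning, never silently 0.
Metrics are kept at full precision and rounded half-up to the reported
decimals only at report time. k-fold summaries carry the Student-t 95%
interval `mean ± t_{0.975,k−1}·std/√k` (sample std, ddof=1) — the t critical
value, not the normal one, is what reproduces published fold-summary
intervals at k=10. k defaults to 5 for CV; the CI arithmetic supports any
k ≥ 2.

In cross-validation the held-out fold serves both as the early-stopping
validation set and the evaluated fold; a nested split would starve
desk-scale folds of patients. Fold metrics therefore have the usual
model-selection optimism of validation-set reporting; the single-split path
(`run_fold` + separate test partition) provides the stricter protocol.

The robustness sweep evaluates a trained model on copies of the evaluation
spectrograms noise-injected at each SNR in {30, 20, 15, 10, 5, 0} dB (one
fixed substream per level) plus a clean reference row.

## Grad-CAM

Class-activation maps are taken at the final convolutional stage (the
feature maps entering pooling): gradients of the target-class logit are
globally averaged over time per channel, the weighted channel sum is
rectified at 0 (standard Grad-CAM; an unrectified map would make a
nonnegative threshold ill-posed), linearly upsampled to spectrogram frames,
and min-max normalized. The map is one-dimensional in time: the first
convolution collapses frequency into channels, so frequency localization
comes from the overlay context. Hot-zone statistics (ratio of frames ≥0.6
and mean contiguous run length) are computed on the normalized map — raw
maxima are of order 10⁻³, which would make an absolute 0.6 threshold
vacuous — while the max/mean summary columns are reported on the raw map to
preserve its scale. Both scales are exported.

## Problem sizes used in tests and the acceptance script

The recovery experiment runs a 20-patient cohort (14 COPD / 6 healthy, the
study's imbalance scaled down) with the desk preset (64 channels), 5-fold
patient-wise CV, ≤10 epochs per fold, and a 30-λ lasso grid with 3 internal
folds; the robustness sweep and Grad-CAM exports reuse a single 70/15/15
split of the same cohort. These sizes are the package's chosen desk-scale
study conditions; the full-size model (1024 channels, 50 epochs, 100-λ grid)
is exercised for its architectural contracts.

## Known limitations

- The synthetic classes are cleanly separable; results on them bound
  pipeline correctness, not clinical accuracy.
- No pretrained speaker-verification initialization (no public checkpoint is
  part of the pipeline's specification); no focal loss; no threshold
  calibration.
- Grad-CAM is a post hoc attribution; the package does not include
  perturbation/occlusion validation of the highlighted regions.
- The network substrate is plain-numpy CPU code: exact and dependency-light,
  but training throughput limits routine experiments to the desk-scale
  preset; the full-size 1024-channel configuration is validated for its
  contracts rather than trained to convergence.
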