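# Methods

`ecgtracks` classifies cardiovascular conditions from ECG recordings along
three parallel tracks that share one signal loader and one evaluation
harness:

1. **Poincaré-image track** — heart-rate-variability geometry rendered as an
   image and classified by a standard 2D backbone (ResNet50 or DenseNet121);
2. **raw-signal track** — 1D convolutional networks (a 12-block plain CNN
   and a 4-block residual network) on the differenced, standardised signal;
3. **feature track** — a catalogue of time-series features fed to a
   Bayesian-optimised XGBoost classifier.

This note records the models, the parameters that matter, the synthetic
data the package is validated on, and the numerical choices made where the
design was genuinely open.

## Signal model and preprocessing

Records are WFDB-dialect files (format-16 integer signal + text header) in
two styles: single-lead 300 Hz rhythm strips with one of four labels
(normal / AF / other / noisy), and 12-lead multi-label records at 257–1000
Hz with demographics in header comments. Signals are stored as 16-bit
integers at 1000 ADC units/mV and converted to millivolts on read.

**Bandpass.** A Hamming-window FIR (1.5·fs taps) passing 3–45 Hz, applied
forward-backward (`filtfilt`), so the response is zero-phase. Single-pass
stopband attenuation at the 0.25 Hz baseline-wander frequency exceeds 20 dB
and is doubled by the two passes; passband ripple at 10 Hz stays within
1 dB.

**R-peak detection** follows the Hamilton pipeline: bandpass, absolute
first difference, 80 ms moving-average integration, candidate local maxima
with a 200 ms refractory spacing, and an adaptive threshold held at 0.45 of
the way from the running noise-peak average to the running signal-peak
average (last 8 peaks each). When the gap since the last beat exceeds 1.5×
the running mean RR, a search-back pass revisits sub-threshold candidates
at half the threshold. Detections are refined to the local maximum of the
filtered signal within ±40 ms. These constants are fixed module-level
values, documented rather than tunable per call.

**NN filtering.** RR intervals become NN ("normal-to-normal") intervals by
dropping anything outside [0.3 s, 2.0 s] or deviating more than 50 % from
the running median of the last five accepted intervals — standard HRV
artifact practice; both bounds are module constants.

**Fixed-length model input.** The public datasets mix lengths from 5 s to
30 min; batched training needs one shape. Records are resampled
(polyphase) to a common rate and cropped/zero-padded: 300 Hz × 30 s for
single-lead style, 500 Hz × 10 s for 12-lead style (the medians of the
respective dataset styles). Both are arguments of `prepare_window`.

**1D model transform.** First-order difference, then per-lead z-scoring.
This makes predictions exactly invariant to lead-wise amplitude scaling and
removes slow offsets; a constant lead maps to zeros with a warning.

## Poincaré construction

The diagram scatters (NNᵢ, NNᵢ₊₁). Rasterisation renders each point as a
radius-2 disc on a 224×224 grid (32×32 in the desk-scale experiments),
adding 0.25 intensity per point and clipping at 1 so cloud density remains
visible. Axis limits are **fixed** at [0.2 s, 1.6 s] by default rather than
data-adaptive: fixed limits keep absolute heart rate visible to the
classifier, which is what separates bradycardia from tachycardia clouds;
per-record limits would normalise that cue away. A config switch restores
adaptive limits. Reversing the NN series transposes the image exactly —
a property the tests exploit as an oracle.

## Architectures

All networks are built on an in-package NumPy layer framework with manual
backpropagation (convolution via im2col + BLAS, batch-norm, max/avg
pooling with ceil-mode right-padding, inverted dropout, Adam). Gradients of
every layer are verified against central finite differences in the tests.

**12-block 1D CNN.** Each block: conv (stride 1, no padding) → batch-norm
(momentum 0.99) → ReLU → max-pool (2/2) → dropout 0.3. Kernel schedule
[20, 5,5,5,5,5, 3,3,3,3,3,3]; channel schedule 256→32, fixed as
[256,256,128,128,128,64,64,64,64,32,32,32] (a monotone taper matching the
stated endpoints — the intermediate values are an interpretive choice).
Head: average-pool (kernel 1, stride 2), flatten, fully-connected. With
ceil-mode pooling the minimum input length is 8332 samples (≈28 s at
300 Hz); shorter inputs raise an error that reports this number.

**1D ResNet.** Stem: conv kernel 15, 64 channels, stride 2 → BN → ReLU →
max-pool 2/2. Four residual blocks (conv→BN→ReLU→dropout→conv→BN, add the
residual, ReLU; kernel-1 projection when shape changes), widths
[64,128,192,256] with within-block kernel 7 — the width reading of the
"65→256" progression; the alternative (kernel progression) is isolated
behind `ResBlock1dSpec`-style constants and is a one-line change. Head:
global average-pool and global max-pool concatenated (512 features), then
fully-connected. The global pools make the model length-independent.

**2D backbones.** Canonical DenseNet121 (growth 32, blocks 6/12/24/16,
~7.0 M parameters) and ResNet50 (bottleneck stages 3/4/6/3, ~23.5 M
parameters), trained from scratch, final layer sized to the class count.
`width_scale`/`depth_scale` shrink growth/width and per-stage depth for
desk-scale training without altering the layout; parameter counts at scale
1.0 are asserted in the tests.

Classifier heads are initialised at 0.1× the He scale so untrained
networks emit near-uniform class probabilities; deep residual stacks
otherwise inflate logits at initialisation.

## Training

Mini-batch Adam (default lr 3·10⁻³, batch 32), cross-entropy for
multiclass and per-class binary cross-entropy for multilabel, early
stopping on validation macro-F1 (patience 10, not before epoch 15), best
validation weights restored. At desk scale a run sees only a few hundred
optimiser steps, which drove two choices:

* **lr 3·10⁻³** rather than the more customary 10⁻³ — the smaller rate had
  not converged within a 30-epoch budget on the synthetic recovery tasks;
* **BatchNorm running-statistic re-estimation** ("precise BN"): after
  training (and before each validation pass for momentum-0.99 models), the
  running statistics are recomputed as an arithmetic mean over the training
  batches with the final weights. Without this, eval-mode predictions lag
  the weights by hundreds of steps and epoch selection is meaningless for
  the momentum-0.99 CNN. BatchNorm default momentum is 0.9; the 12-block
  CNN keeps its specified 0.99.

All randomness (init, batching, dropout) derives from the config seed;
two runs with one seed produce identical epoch-1 losses and identical test
decisions.

## Feature track

The feature catalogue (~214 columns) follows the `group__param` naming
convention so importances aggregate by prefix. It covers distributional
moments, quantiles, autocorrelation, FFT and Welch spectral coefficients,
Ricker-wavelet CWT coefficients, energy-ratio chunks, peak counts,
Lempel–Ziv complexity, change-quantile statistics and linear trend — and
deliberately omits the expensive families: entropy estimators, matrix
profile, CWT peak counting, partial autocorrelation, aggregated linear
trend, and augmented Dickey–Fuller statistics. Undefined values (e.g.
autocorrelation of a constant series) become NaN, then −999 at imputation.
The variance filter (threshold 0, i.e. constants only) is fitted on
training rows and the retained-column list is re-applied verbatim to
validation/test, so no information leaks.

Hyperparameter search: `min_features_to_select` ∈ [10, #features] and
`max_depth` ∈ [2, 100] uniform; `gamma`, `eta`, `scale_pos_weight`,
`reg_lambda`, `reg_alpha` log-uniform over [10⁻³, 10³]. The optimiser is
Gaussian-process expected improvement in the unit hypercube (Matérn 5/2,
random initial design, 256-candidate EI maximisation), capped at a trial
budget. Feature elimination inside each trial is single-shot: fit, rank by
split frequency, keep the top `min_features_to_select`, refit. Boosters use
50 trees at desk scale.

Feature importance is split-frequency ("weight"), normalised to sum 1 and
summed within name-prefix groups, reported with group sizes in descending
order.

## Evaluation and efficiency

Metrics are one-vs-rest per class: precision TP/(TP+FP), sensitivity
TP/(TP+FN), specificity TN/(TN+FP), F1 = 2PR/(P+R); the headline number is
the **macro** (unweighted) average — with the heavy class imbalance of the
public sets, micro averaging would hide the rare classes (micro remains
available). Zero-division convention: a metric with denominator 0 is 1 if
the class produced no errors and 0 otherwise. Cross-validation is
stratified 5-fold over train+validation combined, reporting the mean and
the **population** SD over folds. A per-source table reports macro-F1 and
mean signal length per origin tag.

The efficiency harness times the processing phase (preprocessing / feature
extraction) and the predicting phase separately per record and reports
per-record means plus run-integrated energy. Energy uses a documented
TDP-share estimator — elapsed time × configurable CPU TDP (default 65 W) ×
load share — because no hardware power counters are read; reports carry an
`estimated` flag, and emissions are energy × a configurable grid carbon
intensity (default 0.4 g CO₂/Wh, a typical mixed grid). These numbers are
measurements of this machine and are never compared against published
hardware-specific figures.

## GradCAM

For a chosen convolutional layer (default: last), the class score's
gradient with respect to the feature maps is spatially averaged into
per-channel weights; the weighted map sum is ReLU-rectified, linearly
upsampled to input resolution and max-normalised. Computed in eval mode so
dropout is off and maps are deterministic. The assertable stand-in for
"the model looks at the right place" is a planted-pattern control: class 1
carries a sinusoidal burst in a random 20 %-of-length window; on correctly
classified records ≥50 % of saliency mass must fall inside that window
(measured ≈0.72 mean), and severing the class score from the feature maps
must give an all-zero map.

## Synthetic data: what it does and does not show

Each beat is five Gaussian bumps (P, Q, R, S, T) at fixed offsets from the
R time (R: 1.0 mV, σ 12 ms; P: 0.15 mV, σ 25 ms; T: 0.3 mV, σ 60 ms);
baseline wander is a 0.25 Hz sinusoid (0.1 mV) and measurement noise is
white Gaussian (0.05 mV default). Rhythm classes: sinus (mean RR 0.8 s,
jitter 0.03 s), tachycardia (0.45 s), bradycardia (1.2 s), AF (i.i.d. RR
from a truncated Gaussian with σ = 0.2·mean RR, rejected below 0.3 s, and
no P bump), and a heavy-noise class (0.35 mV). AF's i.i.d. intervals
reproduce the spreading Poincaré cloud; the 12-lead dialect applies fixed
per-lead amplitude scalings and draws rates from {257, 500, 1000} Hz.

What passing these tests shows: the detector, both 1D architectures, the
image track, the feature track, GradCAM and the harness are wired
correctly end to end and can recover known, separable structure. What it
does not show: performance on real ECG — real morphology variation,
ectopy, electrode artifacts, class overlap and inter-patient variability
are all absent, and the synthetic classes are far more separable than
clinical ones. Published-scale scores should not be expected from, or
compared to, these controls.

## Desk-scale problem sizes

The validation experiments are sized for a single CPU: 1D ResNet recovery
uses 1000 records (600/200/200) of 10 s at 300 Hz with `width_scale` 0.25
and ≤30 epochs; the DenseNet–Poincaré experiment uses 700 thirty-second
records rasterised at 32×32 with width/depth scale 0.25; the boosting
track uses 300 ten-second records and 12 search trials; the CNN texture
control uses 120 thirty-second records. The full-width layouts are
audited structurally rather than trained.

## Known limitations

* The NumPy framework is CPU-bound and single-threaded beyond BLAS; it is
  meant for correctness and desk-scale experiments, not large-scale
  training.
* The 12-block CNN's all-max-pooling layout cannot express beat-rate
  counting; it learns texture/morphology contrasts but not rate contrasts
  (verified directly — its loss stays at chance on a pure rate task while
  the ResNet solves it). This is a property of the specified architecture,
  not of the implementation.
* The "efficient" feature list is a curated catalogue, not a bit-exact
  clone of any particular library release; the computed-column manifest
  makes results self-describing.
* Energy figures are model-based estimates, not measurements of hardware
  counters.
* Multilabel training is supported (BCE loss, per-class 0.5 threshold,
  configurable) but the synthetic generator emits one rhythm label per
  record, so multilabel behaviour is exercised with synthetic label
  matrices rather than genuinely co-occurring diagnoses.
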