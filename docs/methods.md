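# Methods

`somnastage` implements an end-to-end comparison of single- versus
multi-channel automatic sleep staging: synthetic polysomnography (PSG)
generation, preprocessing, a hybrid attention network with a capped
class-weighted loss, handcrafted-feature baselines, record-level
cross-validation, and accuracy / Cohen's κ / per-class F1 evaluation over
2/3/4/5-class staging tasks.  This note records the model, its
assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Preprocessing chain

Records are processed in a fixed order: merge signal and labels and
truncate to their overlap → resample to 100 Hz → notch at the line
frequency → band-pass 1–40 Hz → re-reference (when a derivation such as
C3-M2 is requested) → cut into 30 s epochs.  Choices:

* **Filters.** Zero-phase (forward–backward) 4th-order Butterworth
  band-pass and a second-order IIR notch with quality factor 30 — standard
  phase-preserving EEG practice.  A 50 Hz notch is skipped when the
  standardized rate is 100 Hz (the notch would sit at Nyquist); the 1–40 Hz
  band-pass removes that band anyway.
* **Resampling.** Polyphase rational resampling with anti-aliasing; the
  ratios 512→100 and 125→100 are exact.
* **Epoching.** The epoch grid starts at the first annotated onset;
  annotations must be 30 s pages.  N4 (R&K scoring) merges into N3; pages
  labeled outside the five stages (movement, unknown) are dropped; a
  trailing partial epoch is dropped.  Per-stage counts are reported so a
  cohort's epoch bookkeeping is a by-product of the pipeline.
* **Label dialects.** A CSV hypnogram dialect
  (`epoch_index,onset_seconds,stage`) and EDF+ annotations via a
  configurable alias table (e.g. "Sleep stage 4" → N4).  Record exclusion
  lists are configuration, never hard-coded.
* **EDF.** Reading goes through `mne`; writing uses a minimal 16-bit EDF
  writer (physical range per channel from the signal, so round-trip error
  is bounded by range/2¹⁶ per sample).

## Staging tasks and class weights

The five AASM stages map onto 2 (Wake/Sleep), 3 (Wake/NREM/REM),
4 (Wake/Light/Deep/REM) and 5-class schemes; Light = {N1, N2} and
Deep = {N3}, the universal convention.  The training loss is a weighted
cross-entropy with inverse-frequency class weights
w_k = max_j n_j / n_k.  The N1 weight is multiplied by 1.5 (N1 is the
rarest and hardest stage), and all weights are then clipped into
[min w, 3.5 · min w] so that no class weight exceeds 3.5 times any other.
The multiplier is applied *before* capping, and the cap is realized by
clipping — the simplest monotone rule satisfying the stated inequality;
other realizations exist, so this is flagged as a package choice.
Weights are always computed from the training split of the current fold,
never from test data.

## Network architecture

One independent *tower* per channel (no weight sharing), each in three
stages, fused by a softmax classifier head.

**Extractor.** Two parallel 1-D CNN branches over the 3000-sample epoch:
a short-kernel branch (64 kernels, size 50, stride 6; pools 8/2 then 4/4)
for fast activity and a long-kernel branch (64 kernels, size 400; pools
4/2 then 2/2) for slow waves, each followed by one further convolution
(128 kernels, size 7) between the pools and dropout 0.5 after each
pooling stage.  Branch outputs are concatenated along time.  Geometry
choices that were open:

* The long-branch **stride is 50** by default.  A stride of 5 (as
  printed in the source description) cannot produce a concatenated width
  of 80 under any padding, and the rest of the published architecture
  (the 80-neuron feed-forward stack) only type-checks at width 80; with
  stride 50 the branches contribute 64 + 16 = 80 exactly.  The stride
  remains configurable, and an inconsistent geometry fails fast at build
  time.
* Zero-padding of half the kernel size on all convolutions, with the
  branch-1 entry padding (28) and pool paddings tuned once so the
  concatenated width lands on 80; the padding table lives in
  `ModelConfig` and the width is derived, not asserted.
* The number of size-7 convolutions per branch is unspecified upstream;
  one per branch is used.
* Dropout 0.5 is applied after each pooling stage (whether it applies per
  pool or per branch was unspecified).

**Feature optimization.** Squeeze-and-excitation residual blocks, applied
twice: a 1×1 convolution projects 128→30 channels, a second 1×1 conv
30→30, a gate squeezes the 30 channels through FC 30→2→30 with a sigmoid
(gates in (0,1)) and rescales them, and a shortcut (1×1 projection where
the channel count changes) is added.  Causal convolutions (30 kernels,
size 7, left-padded by 6) generate Query, Key and Value, so the Q/K/V
value at time step t depends only on inputs at steps ≤ t; stacking keeps
this property.  Multi-head attention treats the 30 feature channels as
sequence positions with the 80-wide time axis as the embedding, split
over d = 5 heads — the only orientation under which the 80-neuron
feed-forward type-checks; the alternative orientation is not offered as a
config switch because it cannot satisfy the width contracts.  Attention
logits are scaled by **d (the head count), not √d_k**, exactly as the
formula is printed in the source description;
`attention_scale="sqrt_dk"` restores the Transformer convention.  After
attention: add & layer-norm (over the 80-wide embedding), a position-wise
feed-forward 80→80→120→80 with ReLU and 10% dropout on the middle layer,
and a second add & layer-norm.  ReLU is used throughout (the source
names no activation); normalization is layer normalization, standard for
attention stacks.

A note on causality: the attention scores are dot products over the full
80-wide embedding, and the feed-forward mixes the whole embedding, so
strict step-by-step causality holds for the causal Q/K/V convolution
stack (where the design places it), not through the attention product
itself.  The causality tests therefore exercise the full stacked
convolution pathway.

**Fusion.** Tower outputs (30×80 maps) are flattened and concatenated
along the feature dimension — fused width grows linearly with the channel
count — then FC(80) → FC(n_classes) → softmax.  Argmax ties break to the
lowest class index.  The ablated "simplified" model ends each tower at
the SE blocks (no causal attention/feed-forward), with the same fusion
head; it has strictly fewer parameters.

**Initialization and scaling.** Uniform fan-in initialization with a
fixed seed; the model is a pure function of its config.  Inputs in µV are
scaled by a fixed gain of 0.02/µV at the model boundary so typical
(~50 µV) signals enter at order one, which conditions the first
convolutions without altering relative amplitudes between stages or
channels.

## Training

Adam with learning rate 0.001, weight decay 0.001 (added to the
gradient) and AMSGrad; a step schedule halves the rate every 10 epochs.
The number of training epochs and the batch size are not fixed by the
method (defaults 30 and 128, both configurable); desk-scale experiments
use smaller values (below).  Training aborts with a diagnostic on a
non-finite loss.  All randomness (init, batch order, dropout) derives
from the configured seeds, so identical seed and data reproduce identical
final weights bit for bit.

## Evaluation

Overall accuracy is trace(confusion)/total (the standard multi-class
reading of the binary TP/TN form).  Cohen's κ = (Acc − Pe)/(1 − Pe) with
the chance agreement Pe computed from the confusion marginals.  Per-class
precision/recall/F1 are one-vs-rest.  Cross-validation treats whole
records as the fold unit (k-fold) or whole subjects (leave-one-subject-
out); a record-level holdout is provided for scaled-down runs.  Metrics
are reported from the confusion matrix pooled over folds; per-fold
accuracies (and their mean) are also emitted, since it is not derivable
which aggregation a given published number uses.  The no-leakage
invariant — every evaluated epoch comes from a record absent from that
fold's training split — is asserted at run time.

## Baselines

Six features per epoch per channel: mean; sample standard deviation;
spectral energy (integrated Welch PSD, 2 s Hann windows, 50% overlap,
restricted to the filtered 1–40 Hz band); dominant frequency (PSD argmax
in that band); Higuchi's fractal dimension (kmax = 10; ≈1 for smooth
curves, ≈2 for white noise; amplitude-invariant; degenerate constant
input defined as 1.0); and Lempel–Ziv complexity (median binarization,
LZ76 phrase count normalized by n/log₂n so random bits approach 1).
Multi-channel epochs concatenate per-channel features.  Classifiers: an
RBF-kernel SVM (C = 1) on z-scored features (fit on the training split)
and a 100-tree random forest with Gini impurity; class weighting is
realized as per-sample weights for both.  kmax, the binarization rule and
the Welch settings are package defaults — the features are named
upstream, their estimators are not.  One estimator caveat: Higuchi's lag
grid degenerates when a lag equals an exact tone period in samples (every
subsequence of a 10 Hz tone at 100 Hz is constant at lag 10), so
ordering checks on pure tones use kmax = 8.

## Synthetic cohorts

The generator exists so the full analysis runs with no data download; it
emulates the statistical features the method relies on and nothing more.

* **Hypnogram.** A first-order Markov chain over {W, N1, N2, N3, N4, REM}
  with a Wake-dominant, persistent-run default matrix (stationary
  distribution ≈ 39% W, 12% N1, 26% N2, 8% N3, 2% N4, 14% REM — within
  the range spanned by public cohorts, where N1 runs from ~5% to ~14%).
  N4 appears rarely so the N4→N3 merge is exercised.  Records start from
  the stationary distribution: short desk-scale records then behave like
  windows of a night in equilibrium rather than all-Wake onsets.
* **Signals.** Per-channel recipes sum components (sinusoids,
  band-limited noise, windowed oscillation bursts, slow deflections) with
  stage-specific gains: Wake → alpha 8–12 Hz; N1 → theta; N2 → theta plus
  three 2 s spindle bursts at 12–14 Hz; N3/N4 → high-amplitude delta
  (N4 higher); REM → theta.  On EEG, N1 and REM are deliberately
  *identical*, so the N1-vs-REM decision must come from the EOG pair:
  REM carries conjugate eye movements (one shared 1–3 Hz waveform,
  opposite polarity on EOG(L)/EOG(R), 60 µV), N1 carries weaker in-phase
  slow activity (0.5–1.5 Hz, 40 µV), and each EOG channel independently
  suffers low-frequency artifact epochs (70 µV, ~45% of epochs) that mask
  the ocular cue — so one EOG channel often loses the cue while two
  provide redundancy.  EOG channels also carry attenuated (×0.15)
  in-phase EEG crosstalk.  Line interference (8 µV at 50/60 Hz) and slow
  drift (20 µV at 0.2 Hz) are always injected so the filters have
  something to remove.  Sensor noise is 10 µV Gaussian.
* **Determinism.** Every stream is seeded by hashing (seed, record_id,
  epoch_index, stream-name); a record is a pure function of (spec,
  record_id) regardless of generation order.  Shared-stream components
  (conjugate eye movements) draw one waveform across channels.
* **What this does not show.** Band-level structure only: no ECG/EMG,
  no apneas, no spindle/K-complex morphology, no inter-subject
  variability beyond fresh waveform draws.  Passing the desk experiment
  shows the pipeline can exploit channel complementarity when it exists;
  it does not certify real-data accuracy levels.

## Desk-scale experiment sizes

The channel-comparison experiment runs on 60 records × 15 epochs
(900 epochs, 70/30 record-level holdout), training each configuration
for 6 epochs with batch 16 at the published optimizer settings, over
three seeds.  The small batch matters more than the epoch count at this
scale — it is the number of optimizer steps that brings the wider
multi-channel models to convergence.  These sizes are the package's desk
defaults: large enough
that the qualitative ordering EEG+2×EOG ≥ EEG+EOG ≥ max(EEG, EOG) is the
expected outcome, small enough for minutes-scale single-CPU runs.
Training at this scale retains run-to-run variance of a few percentage
points, which is why the ordering is asserted across seeds rather than
per seed.

## Numerical choices

* All network arithmetic is float32; optimizer moments in float64.
* Cross-entropy clamps zero probabilities at 1e-12 (logged).
* Row-stochasticity of transition matrices is validated to 1e-9.
* Attention softmax subtracts the row max before exponentiation.
* EDF physical ranges collapse to ±1 around a flat channel.

## Known limitations

* The network and autodiff engine are implemented in numpy; training is
  CPU-bound and desk-scale, not a large-scale training harness.
* EDF+ annotation reading covers the common "Sleep stage X" vocabularies
  via the alias table but not every archive dialect.
* The causal-attention stack's causality guarantee covers the Q/K/V
  convolution pathway (see above).
* Pooled-vs-fold-mean metric aggregation is emitted both ways; published
  single numbers may use either.
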