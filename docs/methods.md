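# Methods

This note records the modelling assumptions, parameter choices, and
numerical conventions behind `preictal`, and what the synthetic-data tests
do and do not establish about real EEG.

## Problem setting and state model

Seizure *prediction* is cast as binary classification of 10-s EEG windows:
pre-ictal (label 0, the positive class) versus inter-ictal (label 1).
States are derived from expert seizure annotations with fixed time
constants: a 5-min seizure-prediction horizon (SPH) immediately before
onset, the 10 minutes before the SPH as pre-ictal, 30 minutes after offset
as post-ictal, and inter-ictal only at least 2 hours from any seizure
boundary. SPH, ictal and post-ictal windows are excluded from both
training classes; the SPH exists so that a raised alarm leaves interveners
usable lead time, and the 2-h guard keeps the baseline class free of
peri-seizure dynamics.

Collisions between states of closely spaced seizures are resolved by
precedence. Ictal and SPH always win. Post-ictal and pre-ictal can only
collide in one configuration — the pre-ictal window of a seizure reaching
back into the previous seizure's post-ictal period — and there the
pre-ictal window keeps only its non-overlapping remainder (possibly
becoming empty, never an error). Inter-ictal ranks last. Recordings with
no annotated seizures are treated as entirely inter-ictal in single-file
mode; such files exist in clinical corpora and are the natural source of
baseline data. Inter-ictal gaps are evaluated within one file by default;
nothing in the package assumes cross-file clock continuity.

All second-to-sample conversions use floor(t·f_s) with half-open
intervals [start, end), everywhere.

## Preprocessing

Filtering precedes everything else so the linear-filter contract is
untouched by the nonlinear scaling: a zero-phase second-order-sections
notch at 60 Hz (quality factor 30) and a 4th-order Butterworth high-pass
at 1 Hz, both run forward–backward. The contract — ≥ 90 % RMS attenuation
at 60 Hz and 0.3 Hz, ≤ 10 % RMS loss at 10 Hz, no group-delay shift beyond
one sample — is asserted directly in tests, which makes the realization
swappable.

Min–max scaling to [0, 1] is applied per channel, per extracted slice,
with bounds from that slice's own data. A constant input maps to the
target minimum. Fitting bounds per recording rather than on the training
split alone is a deliberate simplification: it mirrors common practice in
this literature, and because bounds are per-channel affine constants it
cannot leak class structure, only amplitude scale.

Windowing uses n = floor((N − w)/hop) + 1 with w = 2560 samples (10 s at
256 Hz). The minority class (by total duration; pre-ictal on ties) is slid
at 50 % overlap (hop 1280), the majority class tiled without overlap. This
brings the class ratio into [0.5, 2] whenever the raw duration ratio is
within [1, 4]. Fractional hops are rounded to the nearest sample. Each
epoch is reshaped row-major to a [channels × 10 × 256] grid (row i holds
second i), the inverse reshape being exact.

The 6:2:2 split is performed in two stages (hold out 20 % test, then 25 %
of the remainder as validation), both stratified by class so validation
and test ratios match the pool. The split is seeded and deterministic.

## Classifier

The network is dual-branch. The convolutional branch processes the grid
(1×1 conv 22→22, 3×3 conv 22→44, batch norm, 2×4 max-pool, LeakyReLU,
3×3 conv 44→5, batch norm, 2×4 max-pool, LeakyReLU). Convolutions are
valid (unpadded, stride 1); pooling uses stride equal to the pool size
with floor division — the only reading consistent with the reference
output dimensions (8→4, 254→63). The recurrent branch reads the same
epoch as a sequence of 22 channel-steps with 2560 features each, through
stacked BiLSTMs of per-direction hidden sizes 640/320/80/20/1; a BiLSTM's
output width is twice its hidden size. This parallel-branch featurization
is an inference — it is the unique reading that reproduces every printed
intermediate dimension, including the 119 = 5·1·15 + 22·2 fused width —
and is flagged as such. The fused vector maps linearly to two logits.

Layers are numpy with hand-written backward passes, each verified against
central-difference gradients in the test suite (float64, atol 1e-5/1e-6).
Batch norm normalizes over (batch, height, width) per channel with
momentum 0.1 and eps 1e-5; a batch of one is safe because spatial extent
remains. LeakyReLU slope defaults to 0.01 (configurable; the reference
leaves it unstated). Initialization: He-style normal for conv/linear,
uniform ±1/√H for LSTM weights, all from one seeded generator, so two
builds with equal seeds are bit-identical (checksummed in tests).

Training uses softmax cross-entropy and Adam (β = 0.9/0.999, eps 1e-8)
with coupled L2 weight decay (decay·param added to the gradient, the
common convention), plus reduce-on-plateau learning-rate scheduling
(factor 0.1, patience 10 — unstated in the reference, exposed in config).
Reference hyperparameters: learning rate 1e-4, batch 128, weight decay
0.9, seed 42, epoch cap 250 with the trend-test stop underneath.

## Cox–Stuart early stopping

For a window x₁..x_n, c = ⌊n/2⌋ pairs (xᵢ, x_{i+⌈n/2⌉}) are formed — the
middle element is dropped for odd n; the printed pair list in the source
material is internally inconsistent for odd n, and the standard convention
agrees with its own c formula. Zero differences are discarded from the
effective trial count m (standard sign-test tie handling). The one-sided
p-value is the exact Binomial(m, ½) lower tail over k = min(num₊, num₋),
computed with integer binomial coefficients and exact rational division
(stable to m ~ 10⁴; no normal approximation). Verdicts at α = 0.1:
increasing iff num₊ > num₋ and p ≤ α, decreasing symmetric, otherwise no
trend; equal sign counts always yield no trend.

The controller appends each epoch's validation loss, updates the best
loss (resetting the stop-vote counter on improvement, before the same
epoch's trend vote), and once epoch > W_p tests the last W_p losses. An
increasing/no-trend verdict increments the counter, a decreasing verdict
resets it, and W_p consecutive votes stop the run. W_p is never stated
numerically in the source material; the default is 10. Consequences
asserted in tests: a noiseless decreasing curve never stops; a plateau
stops at epoch 2·W_p; a v-shaped curve stops only after its minimum. The
separate "increasing"/"flat" counters of the reference pseudocode are
merged into one stop-vote counter (the stop rule treats both identically);
both raw counts are still recorded.

## Hyperparameter search

The search space is learning rate ∈ [1e-5, 1e-2] (uniform), batch size
∈ {64, 128}, epochs ∈ [50, 200], weight decay ∈ [0.5, 1.0] (log-uniform),
5 trials, objective = the trial's best validation loss (ties broken by
earlier epoch). The TPE-style sampler splits history at the γ-quantile
(γ = 0.25 by default, 0.15/0.25 being the customary choices), fits
per-dimension Gaussian-mixture densities to the good and bad sets
(normal-reference bandwidth 1.06·s·n^(−1/5), floored at a tenth of the
dimension's span so single observations still define densities;
log-transformed for weight decay; add-one-smoothed frequencies for batch
size), scores a seeded 24-candidate pool by the aggregate log-ratio
Σ log l − log g, and returns the argmax. With fewer than two observations
it falls back to random sampling. Pruning is plain successive halving over
geometric budgets r_min·η^s, s = 0..s_max = ⌊log_η(R/r_min)⌋, resuming
model and optimizer state between rungs and keeping the best 1/η at each;
the full multi-bracket orchestration is deliberately simplified to one
bracket, with the bracket-count formula implemented exactly. An external
optimizer can be plugged in through the `objective` callback, which must
return a completed trial record for a sampled assignment.

## Evaluation statistics

Pre-ictal is the positive class. Undefined ratios (zero denominators) are
reported as missing, never silently zero. Cross-model comparisons from
fold-level summaries use Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom, and the pooled-SD effect size
|d| = |m₁−m₂|/√((s₁²+s₂²)/2) — the equal-group-size form, which
reproduces all nine published effect sizes in the bundled benchmark to
four decimals, and is therefore adopted as normative. Bands: |d| < 0.2
negligible, < 0.5 small, < 0.8 medium, ≥ 0.8 large; boundary values go to
the higher band. Summary-table means are rounded half-up at each column's
printed precision.

## Synthetic data

Each channel is a sum of: a 1–4 Hz sinusoid bank (1.5/2.5/3.5 Hz, random
phases) whose amplitude is the class gain — pre-ictal spans get the
pre-ictal gain (default 1), inter-ictal spans the inter-ictal gain
(default 4), all other time the mean of the two; a 60 Hz mains sinusoid
(amplitude 1); a 0.3 Hz drift sinusoid (amplitude 1); unit-variance
1/f-shaped noise and white noise, both scaled by noise_sd (default 0.5).
Class spans come from the package's own segmentation rules applied to the
config's seizure events, so generator and segmenter cross-validate each
other. Everything is driven by one seeded generator; identical
(config, seed) gives bit-identical output.

The default gain ratio of 4 encodes the qualitative observation that
inter-ictal activity carries more low-frequency energy than pre-ictal
activity; no quantitative characterization exists to calibrate against,
so the ratio is a free design choice made once. Amplitudes are set so the
classification task is learnable by the reduced network in minutes on one
CPU.

The reduced-scale study dataset is two recordings: a 3900-s recording with
seizures at (1000, 1050) and (3850, 3890) s — spaced so both full 10-min
pre-ictal periods survive the precedence rules — contributing 238
pre-ictal windows at 50 % overlap, and a 2050-s seizure-free recording
contributing 205 inter-ictal windows, 443 balanced windows total. The
reduced network keeps the dual-branch topology with conv channels (8, 4)
and BiLSTM hidden size 8 (~167k parameters), trained with learning rate
1e-3, batch 32, weight decay 1e-4, 2 folds, ≤ 12 epochs. These sizes are
the package's chosen desk-scale study conditions.

What passing tests show — and what they do not: the synthetic signal has
no seizure morphology, no artifacts (blinks, EMG, electrode pops), no
nonstationarity beyond the class gain, and a *linearly separable* class
contrast in band power. Perfect accuracy on it demonstrates that the
pipeline is wired correctly end to end (segmentation, filtering, scaling,
windowing, training, early stopping, evaluation), not that the classifier
would reach comparable accuracy on clinical EEG; the label-shuffled
control (accuracy ≈ 0.5) confirms the score is earned from the signal,
not leaked through the pipeline.

## Numerical conventions and degenerate inputs

EDF encoding quantizes each channel to 16 bits over a symmetric physical
range just above its peak; write/read round trips are exact to one
quantization step and the reader is cross-checked against an independent
EDF implementation in tests. Constant signals scale to the target
minimum. Empty window stores round-trip. Slices shorter than one window
yield zero windows; zero-length state intervals are dropped. Pooling
crops trailing rows/columns that do not fill a window. Non-finite losses
abort training with a diagnostic rather than propagating NaNs.

## Known limitations

No ROC/AUC or event-based alarm metrics (false alarms per hour); no
artifact rejection, montage re-referencing, or resampling; no multi-class
(4-state) task; single-bracket Hyperband; training is single-threaded
CPU numpy, adequate for the reduced scale it targets but not for
full-corpus training.
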