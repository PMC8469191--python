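# Methods

## Problem and model

`hemowave` estimates continuous hemodynamic pressure waveforms from a single
non-invasive lead-II ECG. Two regimes are covered: a *cardiovascular* system
mapping one 2-s ECG window to three simultaneous pressure windows — arterial
(ABP), central venous (CVP) and pulmonary arterial (PAP) — and a *cerebral*
system mapping the ECG window to intracranial pressure (ICP). All pressures
are in mmHg, ECG in mV.

The regressor is a 1D multi-atrous U-Net convolutional autoencoder
(MA-UDCAE). Each encoder level applies a **multi-atrous block** — parallel
same-padding convolutions over the same input at several dilation rates
(default 1, 2, 4; kernel 3), concatenated along the channel axis — followed
by window-2 max pooling. A branch with kernel *k* and dilation *d* spans
`1 + (k-1)·d` samples, so the parallel branches see the signal at several
temporal scales at once without extra parameters. The decoder mirrors the
encoder with nearest-neighbour ×2 upsampling, and named skip connections
concatenate encoder feature maps into the decoder at matching resolution
(`skip_L1 … skip_Lk`), optionally including the raw input at full resolution
(`input_skip`). Two or three plain convolutions form the head; the output
activation is linear, so predictions are unclipped and can go negative —
negative pressure predictions are reported, not hidden.

Geometry presets:

| profile    | window        | levels | outputs | skips |
|------------|---------------|--------|---------|-------|
| cardio     | 2 s × 128 Hz = 256 samples | 4 (3 in the fast runs) | ABP, CVP, PAP | skip_L1..L4 + input_skip |
| cerebral   | 2 s × 50 Hz = 100 samples  | 2 | ICP | skip_L1, skip_L2 |

The cerebral network is shallower because a 100-sample window is divisible
by 2² but not 2⁴; the builder rejects any `in_len` not divisible by
`2^levels`. The cardiovascular sampling rate is 128 Hz so that a 2-s window
(256 samples) supports up to four pooling stages; the cerebral rate of 50 Hz
matches the native rate of clinical ICP recordings of this kind.

Filter counts, kernel sizes and dilation rates are free design choices here
(sized for CPU-scale experiments, all config-overridable): base 8–16 filters
per branch doubling per level (capped at 64), merge = channel concatenation,
max pooling for downsampling, nearest-neighbour upsampling before each
decoder block.

## Training

Mean absolute error over all output samples (scaled units), Adam, default
learning rate 2e-3 and batch size 16 (chosen for good 30-epoch convergence
on the synthetic corpus at CPU scale), fully seeded. Every epoch records
training and validation loss; the weights of the epoch with the lowest
validation loss are kept (**checkpoint system**; ties break to the earliest
epoch). Inputs and targets are min–max scaled to [0, 1] with per-channel
affine scalers fit on the training pool only; predictions are mapped back to
mmHg through the inverse scaler. A constant channel degenerates to unit gain
with the constant as offset.

The evaluation protocol is **inner-loop cross-validation**: one random test
split is fixed first (default 20 % of windows), then k folds (default 5)
rotate train/validation over the remaining pool. Every pool window validates
exactly once, fold sizes differ by at most one, fold assignment depends only
on the seed (ids are sorted before shuffling), and every fold's network is
evaluated on the same fixed test set. Windows are pooled across subjects
before splitting, so the split is window-wise, not subject-wise — a known
optimistic bias of this protocol that the package reproduces deliberately.

The whole network stack (dilated conv, pooling, upsampling, concatenation,
MAE loss, reverse-mode gradients, Adam) is implemented in NumPy inside
`hemowave.nn`; gradients are verified against finite differences in float64
in the test suite. Training runs in float32.

## Windowing and screening

Records tile into consecutive non-overlapping half-open windows
`[start, start+n)` from sample 0; a trailing partial window is discarded,
and any window touching the record's exclusion mask is dropped. Quality
screening is rule-based (the stand-in for manual visual curation, which does
not scale): a window is rejected if any sample is non-finite, any channel's
variance falls below 1e-6 (flat-line), or any pressure leaves its
physiological gate (ABP 10–300, CVP −10–50, PAP −5–120, ICP −10–100 mmHg,
ECG ±10 mV). The reason code names the rule and channel.

## Fiducials and evaluation

From each 2-s window: systolic = window maximum and diastolic = window
minimum for ABP and PAP; mean = arithmetic window mean for CVP and ICP. No
peak detection or smoothing — this raw rule is noise-sensitive by
construction (noise inflates systolic and deflates diastolic values), and
that sensitivity is part of the method being reproduced.

Metrics: Pearson's R, RMSE and MAE, computed both at waveform level (all
samples of all test windows pooled into one vector pair; switchable to
per-window averaging) and at fiducial level (one value per window). Fold
tables report mean and *sample* (n−1) standard deviation across folds — the
sample convention is what reproduces the published fold tables at three
decimals. Bland–Altman agreement uses differences `prediction − reference`
(direction recorded in every summary, switchable), bias = mean difference,
limits of agreement = bias ± 1.96 × sample SD.

## Synthetic data generator

The generator exists so the entire pipeline is testable without external
recordings. One beat train per subject drives all channels:

- **Beats**: RR intervals ~ Normal(60/HR, jitter); `irregular_rr` multiplies
  the jitter sixfold; `premature_beats` inserts early beats (55 % of the
  base interval, tagged) followed by a compensatory pause.
- **ECG**: per beat a P-Q-R-S-T sum of Gaussian bumps. Premature beats get a
  widened (optionally inverted) R and no P wave.
- **ABP/PAP**: a per-beat pulse — half-cosine systolic upstroke (18 % of the
  beat) then exponential diastolic decay rescaled to end exactly at zero —
  scaled so each beat's maximum equals the systolic target and its minimum
  the diastolic target, delayed by the pulse transit time. Premature beats
  get 55 % pulse amplitude (reduced stroke volume).
- **CVP/ICP**: low-amplitude multi-peak beat templates (a/x/c/v-like and
  P1/P2/P3-like waves, alternating signs), made exactly zero-mean per beat
  so the series mean equals the mean target; plus a respiratory sinusoid.
- Gaussian noise is added last, per channel.

Fiducials of the noise-free signal are therefore analytic: per-beat max/min
equal the systolic/diastolic targets and series means equal the mean
targets, which is what the fiducial-correctness tests assert (within 1 %,
the slack covering sampling discretization and partial beats at window
edges).

Two couplings make the single-lead ECG → pressure mapping *well-posed*, both
chosen to mirror relationships reported in the clinical literature rather
than to be clinically accurate: (1) ECG morphology encodes the subject's
pressure targets (R amplitude tracks systolic ABP, S depth systolic PAP,
P amplitude mean CVP, T amplitude mean ICP, Q depth diastolic ABP); (2)
pulse transit delay decreases deterministically with systolic pressure
within 0.14–0.22 s (the PTT–BP relationship). Without these, between-subject
pressure levels would be unidentifiable from the ECG and "learnability"
would be meaningless.

Default subject ranges (uniform draws): HR 55–95 bpm, SBP 95–175 / DBP
55–95 (DBP conditioned ≥ 20 mmHg below SBP), PAP 18–45 / 6–18, mean CVP
4–12, mean ICP 8–25 mmHg, respiration 10–18 breaths/min. Noise defaults:
ECG 0.01 mV; ABP 0.4, PAP 0.25, CVP/ICP 0.15 mmHg; ABP respiratory
amplitude modulation 2 %, CVP/ICP additive respiratory sinusoid 0.5 mmHg.

**What the generator does *not* emulate** — and hence what passing tests do
not show about real data: measurement artifacts and electrode motion, beat
morphology variety (the five-bump beat is fixed up to the couplings),
pathology-specific waveforms, baseline drift, the true (weak, noisy,
confounded) ECG–hemodynamics association in patients. Tests passing here
demonstrate that the pipeline and network are correct and that the
architecture can learn a deterministic beat-synchronous mapping; they say
nothing about clinical performance.

## Ablation harness

Skip connections are removed cumulatively, deepest merge first
(cardiovascular: `skip_L4, skip_L3, skip_L2, skip_L1, input_skip`, giving
the full model plus five variants; cerebral: `skip_L2, skip_L1`, full plus
two). All variants share the corpus, scalers, fold assignment and seeds, and
each records per-epoch training and held-out-test MAE curves. Removing a
skip narrows the following decoder convolution, so the parameter count is
non-increasing along the sequence.

## Problem sizes and numerical choices

The learnability experiments use 40 subjects × 60 s per profile (1,200
2-s windows), a levels-3 / base-8 cardiovascular network and the levels-2
cerebral network, ≤ 30 epochs — sizes at which the held-out pooled waveform
correlation exceeds 0.9 on ABP and ICP on an ordinary CPU in minutes. The
ablation study runs 5 epochs per variant. The demo pipeline (3 subjects,
2 epochs, k = 2) exists for smoke tests and byte-level determinism checks:
all randomness descends from a single seed, so a rerun reproduces identical
metrics JSON.

Degenerate inputs are handled explicitly: constant channels in scalers (unit
gain), k = 1 cross-validation (train on the whole pool with the internal
validation split; fold STD 0), empty fiducial windows and zero-variance
correlations raise informative errors. Checkpoint ties break to the earliest
epoch; non-finite training loss aborts with a diagnostic rather than
continuing.

## Known limitations

- The NumPy training loop is single-process and CPU-bound; it is sized for
  the bundled experiments, not for hour-scale corpora.
- Window-wise (not subject-wise) test splitting copies the evaluated
  protocol and inherits its optimism.
- The raw max/min fiducial rule is noise-sensitive by design.
- The synthetic corpus is a verification instrument, not a clinical
  benchmark; results on it do not transfer to patient recordings.
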