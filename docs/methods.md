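# Methods

This note documents the models, conventions and design choices behind
`lungsound`, in the spirit of a methods appendix: what the code computes,
which knobs matter, what the synthetic data does and does not emulate, and
where genuinely open choices were fixed.

## 1. Problem setting

Respiratory sounds recorded at the chest wall are classified into three
clinically central categories:

* **normal** — vesicular breath sound: band-limited noise modulated by the
  breathing cycle;
* **wheeze** — a continuous musical (tonal) component, ≥ ~100 ms, dominant
  frequency roughly 100–1000 Hz, superimposed on the breath sound;
* **fine crackle** — brief (≤ ~20 ms) discontinuous damped-oscillation
  transients, predominantly inspiratory.

The pipeline targets *simultaneous multi-position* recordings: one mono
sensor per auscultation site, up to 12 sites named `{F,B} × {RUL, RML, RLL,
LUL, LML, LLL}` (anterior/posterior × right/left upper/mid/lower lung). The
scientific question the evaluation protocol addresses is whether fusing
channels improves classification over any single channel.

Class labels map to integers 0 = normal, 1 = wheeze, 2 = fine crackle
everywhere.

## 2. Synthetic cohort generator

Clinical multi-channel auscultation corpora are access-restricted, so the
package generates cohorts with the statistical structure the pipeline
relies on. The generator is first-class, tested code — not a fixture — and
all tests and benchmarks run on it.

**Breath envelope.** One cycle = inspiration (40% of the period, amplitude
1), expiration (35%, amplitude 0.6), pause (25%, amplitude 0); each phase a
squared half-sine, cycle amplitudes jittered by 5% Gaussian noise. Breath
rate is per-subject, uniform in 12–20 cycles/min.

**Source construction.** The *breath* component is the envelope times
noise band-passed to 100–1000 Hz (4th-order Butterworth). The
*adventitious* component is class-dependent:

* wheeze: a sinusoid at a subject-specific frequency (uniform 200–800 Hz),
  amplitude-modulated by the envelope and gated to envelope > 0.25 — the
  gate keeps tonal segments ≥ 100 ms because the envelope varies on the
  breath timescale; tone RMS is set to 2× the breath RMS within active
  regions (√2 amplitude factor).
* fine crackle: per inspiration, a Poisson(density) number of exponentially
  damped sinusoids (centre frequency uniform 200–1000 Hz, duration uniform
  8–20 ms, decay to 1% over the burst). Burst amplitude is 1.2–2.0× the
  breath component's *peak* — fine crackles are distinctly audible above
  the vesicular base, and peak-relative scaling is what makes a
  local-contrast transient detector and the downstream classifier able to
  find them. Per-subject density is uniform in 6–10.

The summed source is peak-normalised to 0.9.

**Multi-channel construction.** Every channel derives from the one shared
source: per-position gain (uniform 0.7–1.0), per-position delay (uniform
0–3 ms), a mild position-dependent one-pole low-pass "tilt" (cut-off 1800 /
1500 / 1200 Hz for upper/mid/lower fields — deeper sites sound darker), and
independent Gaussian sensor noise at a configurable SNR (default 30 dB,
defined against the clean channel RMS). The optional `cue_gains` map scales
only the adventitious component per position; cohorts can thereby plant
class cues on specific channels while the breath stays shared, which is the
construction behind the channel-complementarity benchmark.

**Cohorts.** Default class proportions mirror a strongly imbalanced ward
population, 1827:447:43 (normal : wheeze : fine crackle, ≈ 0.789 / 0.193 /
0.019); counts use largest-remainder rounding with ties to the lower class
index. Per-subject seeds spawn from the cohort seed via
`numpy.random.SeedSequence`, so cohorts are bit-reproducible and any
subject can be regenerated in isolation. Benchmarks use balanced
proportions so the chance level is 1/3.

**What the generator does not emulate.** Real airway acoustics (no
physiological model), inter-subject anatomy, device transfer functions,
real ICU noise (contamination is synthesized as tones + filtered noise),
polyphonic wheezes, coarse crackles/rhonchi, or label noise. Passing tests
on this generator therefore demonstrates that the *pipeline* is correct and
that the *protocol* can detect multi-channel gains when they exist — it
does not certify clinical performance.

## 3. Augmentation

`mix_background` is the exact convex combination
`(1−w)·I_in + w·I_noise`, `w ∈ [0,1]`; no normalisation is applied, so the
identity at `w ∈ {0,1}` and the bound `|I_out| ≤ 1` for bounded inputs are
exact. Background sources are synthetic ICU-style contaminations:
ventilator hum (a 45–75 Hz fundamental with two harmonics plus low-passed
noise), speech-band babble (120–900 Hz noise, slow amplitude modulation)
and rustling (sparse Hann-windowed wide-band bursts).

Time stretching uses an STFT phase vocoder (window 256, hop 64, magnitude
interpolation, per-bin phase advance); pitch shifting resamples by
2^(semitones/12) and restores the duration with the same vocoder, limited
to ±12 semitones. The remaining transforms are elementwise: seeded additive
Gaussian noise, amplitude gain, circular time shift, and random sample
masking without replacement.

Rebalancing applies `multiplicity[class]` extra augmented copies per
original ("n augmentations" is read as n additional copies, so wheeze ×31
total under the 30/4 policy). Each copy draws ONE transform uniformly from
the enabled list with parameters from configured ranges and applies it with
identical parameters (and identical noise realisations) to every channel,
preserving channel alignment. Copies are flagged `augmented=True` and carry
`<subject>-aug<k>` ids.

By default rebalancing runs *after* the train/val/test split, on the
training partition only: augmented near-duplicates of one recording must
not straddle the evaluation boundary. The pipeline config can reproduce the
augment-then-split ordering (`augment_after_split: false`) for comparison;
the subject-grouped split then still keeps each original and its copies in
one partition.

## 4. MFCC features and fusion

Extraction parameters: 4 kHz processing rate (inputs are resampled), 25 ms
window (100 samples), 10 ms hop (40 samples), 40 mel filters, keep cepstral
coefficients 1–13. Conventions the definition leaves open were fixed once:

* frames without centre padding, `n_frames = 1 + ⌊(N − 100)/40⌋`;
* periodic Hann window; FFT size 128 (next power of two ≥ window);
* HTK mel scale `2595·log10(1 + f/700)`, unit-peak triangles spanning
  0–2 kHz (at these settings every triangle covers at least one FFT bin);
* `log(E + 1e-12)`; orthonormal DCT-II along the mel axis.

Dropping the 0th coefficient makes features invariant to global gain up to
the log floor; for broadband inputs whose mel energies sit far above the
floor the invariance is numerically ~1e-8. An all-zero signal yields
exactly zero kept coefficients (the log of a constant floor is constant,
and the DCT of a constant is zero beyond order 0).

Per-channel matrices are stacked row-wise in a fixed canonical position
order (anterior before posterior; right before left; upper → mid → lower),
independent of input enumeration order. The stacked `13·C × n_frames` grid
is resized to the fixed 128 × 350 network input with a separable bilinear
(triangle-kernel) filter in the pixel-centre convention; for downscaling
the kernel support widens to the scale factor, as high-quality image
resizers do — plain two-point interpolation would silently drop most
one-frame crackle transients when mapping ~1000 frames onto 350 columns.
At equal sizes the resize is the identity. The resized grid is standardised
to zero mean and unit variance (variance floored; constant grids map to
zeros). The raw time-series baseline input stacks channel waveforms as an
`N × C` grid and goes through the same resize.

## 5. Classifier

A ResNet-18-style backbone: 7×7 stride-2 convolution + batch-norm + ReLU +
3×3 stride-2 max-pool, then four stages of two residual blocks with 3×3
convolutions, stride 2 at stage entries. A residual block computes
`y = F(x, W) + shortcut(x)` with `F = conv→bn→relu→conv→bn` and a 1×1
projection shortcut when shape changes; no activation follows the addition,
so zeroing F's parameters makes the block exactly the identity.

Stage widths default to (16, 32, 64, 128) — the canonical (64…512) widths
give an ~11 M-parameter network, which is outsized for a 3-class problem;
the narrowed stack lands at ~0.75 M and widths remain configurable
(`describe` prints the layer table and exact count). After the stages,
average pooling collapses the frequency (row) axis only, leaving a
(channels × 11)-column sequence; the LSTM variants feed it to a single
64-unit LSTM (forget-gate bias 1) and classify from the final hidden state,
the plain-CNN variants flatten it. The head is dropout 0.3 → fully
connected → softmax over 3 classes. Argmax ties resolve to the lowest class
index; inference always runs with dropout off and batch-norm in
running-stats mode.

The four variants (`cnn_ts`, `cnn_lstm_ts`, `cnn_mfcc`, `cnn_lstm_mfcc`)
share the backbone; only the input pathway (raw time-series vs MFCC) and
the temporal module (flatten vs LSTM) differ.

Everything — convolutions (im2col + BLAS matmul), batch-norm, pooling,
LSTM backpropagation through time, dropout, softmax cross-entropy and the
RAdam optimizer (rectification threshold ρ > 4, ε = 1e-6) — is implemented
directly on numpy in float32, with backward passes verified against
finite-difference gradients in the test suite's development history and
against hand-rolled convolution loops in the suite itself.

Class-activation maps are gradient-weighted: channel weights are spatial
means of the class-score gradient at the last residual stage; the weighted
ReLU-rectified sum is bilinearly upsampled to 128 × 350 and min–max
normalised, with an all-zero map returned when no positive evidence exists.

## 6. Training protocol

Full-scale settings: 70:15:15 stratified split (largest-remainder per
class, grouped by subject so augmented copies follow their original), 50
epochs, batch 20, categorical cross-entropy, RAdam(ε=1e-6), learning rate
decaying linearly from 1e-4 at epoch 0 to 5e-5 at the final epoch. The
checkpoint with the best validation loss is kept. An ensemble = 3 sessions
with seeds `base+0, base+1, base+2`; reported metrics are the mean ± sd of
the sessions' evaluation metrics (an alternative reading — averaging
predicted probabilities — is deliberately not the default). Non-finite
loss aborts with a distinct `DivergenceError`.

Determinism: model initialisation, batch shuffling and dropout all derive
from the session seed; repeated runs give bit-identical parameters on the
same platform/BLAS.

## 7. Evaluation

Metrics come from the 3×3 confusion matrix via one-vs-rest reduction:
per-class accuracy, precision, recall (=sensitivity), specificity and F1,
macro-averaged; 0/0 cells are reported as 0 and flagged so reports stay
total. The aggregate table's `accuracy` column is the plain trace/total
accuracy; the multi-class reduction for the other single-scalar metrics is
the macro mean — a convention this package fixes explicitly since
"sensitivity of a 3-class classifier" is otherwise ambiguous.

The ablation grid retrains the full pipeline per position subset. The
subject split is computed once on the complete recordings and reused for
every subset, and all subsets start their ensembles from the same base
seed: rows differ only in which channels the features were built from.

## 8. Reduced-scale benchmarks

CPU-scale study conditions, fixed once in `lungsound.benchmarks`:

* **Learnability.** 300 balanced recordings at 30 dB SNR with the default
  strong class parameters, 70:15:15 split, one session of 10 epochs at
  batch 20, narrow widths (8, 16, 32, 64), learning rate 3e-3 → 1.5e-3.
  The reduced run's learning rate is necessarily larger than the full-scale
  1e-4: a 10-epoch, ~100-step session sits in RAdam's rectification window
  and the full-scale rate would leave the model at chance. Expected
  behaviour: test accuracy far above the 1/3 chance level (the acceptance
  suite requires > 0.80).
* **Channel complementarity.** 240 balanced training recordings whose
  wheeze tone is planted on the BRUL and BRLL channels and whose crackle
  bursts on BLUL and BLLL (`off_cue_gain = 0`), so no single channel sees
  both classes; a separately synthesized 180-recording cohort serves as the
  test set, shrinking evaluation variance without extra training cost.
  Three sessions of 16 epochs at batch 10 per arm (batch 10 doubles the
  optimizer steps per sample-pass relative to batch 20, which the small
  cohort needs). Arms: all four channels; the strongest single channel
  (BRUL, which carries the wheeze cue — a conservative comparator); and a
  negative control in which every recording's four channels are literal
  copies of its BRUL channel, where any "multi-channel" gain would be
  spurious. Expected behaviour: the 4-channel mean beats the single-channel
  mean by a clear margin; the control shows no comparable gain. A caveat
  found while designing this benchmark: with ~90-example evaluation sets, a
  classifier can ride spurious sample correlations to apparent 0.6-level
  discrimination of classes it provably has no information about, which is
  why the evaluation cohort is 180 recordings and the margin threshold is
  far below the expected ~0.1–0.2.

## 9. Numerical and degenerate-input conventions

* WAV: 16-bit PCM quantised as `round(x·32768)` clipped to int16 (round-trip
  error ≤ 2⁻¹⁵) or IEEE float32 (bit-exact round trip); stereo files are
  rejected, never down-mixed; 8/16/32-bit PCM and float are the accepted
  encodings.
* Recordings are trimmed from the end / zero-padded at the end to the
  requested duration; resampling is polyphase with duration preserved to
  one sample period.
* Cohort assembly returns only subjects possessing ALL requested positions;
  an empty selection warns rather than silently returning `[]`.
* Degenerate 1×N / N×1 grids are rejected by the model-input resize; the
  single-channel raw-waveform baseline duplicates its one column first.
* Metric 0/0 cells → 0 with a flag; empty confusion matrices are errors.
* The variance floor in input standardisation is relative (1e-6 of the
  grid mean's magnitude), so constant grids map to zeros without
  amplifying resize round-off.

## 10. Known limitations

* The synthetic classes are far more stereotyped than clinical audio;
  absolute accuracies here say nothing about clinical accuracy.
* The numpy network trains on one CPU at small-cohort scale; the
  full-scale 50-epoch/3.6 M-parameter regime, while expressible, is not
  practical without a GPU framework behind the same interfaces.
* Phase-vocoder transforms introduce the usual transient smearing; crackle
  timing is preserved only to within the 64-sample synthesis hop.
* The benchmark margins are seed-robust at the stated sizes but single
  seeds of the *single-channel* arm can fluctuate by ±0.08; conclusions
  should always be drawn from the 3-session means.
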