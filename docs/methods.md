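# Methods

## Problem and model

Slow eye movements (SEMs) are slow, rolling, conjugate horizontal eye
movements (0.2–0.6 Hz, 20–200 µV, lasting more than 2 s) that mark the
transition from wakefulness to sleep.  They appear with opposite phase on
the two outer-canthus electrodes Hl and Hr, so the difference trace
HEOG = Hl − Hr doubles the ocular component and cancels common-mode EEG,
while the sum HSUM = Hl + Hr cancels the ocular component and retains
EEG-like activity (including the occipital alpha rhythm that attenuates
around sleep onset).  Detection is cast as binary classification of 3-s
bimodal windows: modality 1 is the median-smoothed HEOG, modality 2 the
baseline-corrected HSUM (or O2 when an occipital electrode is available).

The detector (PMMCT — parallel multimodal CNN-Transformer) processes the
two modalities in parallel branches.  Each branch applies two
convolution–batch-norm–ReLU layers with max pooling, adds a fixed
sinusoidal positional encoding, runs N = 2 post-norm Transformer encoder
layers (h = 2 heads of scaled dot-product self-attention,
`Softmax(QKᵀ/√d_k)V`, plus a position-wise feed-forward network
`max(0, xW₁+b₁)W₂+b₂`, each followed by residual Add & Norm), and
reduces the sequence by global average pooling.  The two d-dimensional
branch vectors are concatenated (2d features) and classified by
FC(ReLU) → dropout → FC(2) → softmax.

Class imbalance (SEM windows are ~10% of the data) is handled by
inverse-frequency class weights `w_i = N / (c·N_i)` inside the weighted
cross-entropy `L = −Σ w_i y_i log(ŷ_i)` (mean reduction over the batch).
These weights satisfy `Σ (N_i/N) w_i = 1` identically and reduce to unit
weights for balanced data.

## Training protocol

Adam (β₁ = 0.9, β₂ = 0.999), initial learning rate 5·10⁻⁴, minibatch
128.  The learning rate is multiplied by 0.2 whenever validation loss
fails to improve for 3 consecutive epochs (floored at 10⁻⁶); training
stops when validation accuracy fails to improve for 10 epochs, and the
best-validation-accuracy weights are restored.  The final-fit validation
set is the chronological last 10% of the training block.  Data are split
chronologically: the first ⌈0.7 n⌉ windows train, the remainder tests;
cross-validation folds are five contiguous time blocks of the training
portion (shuffled folds would leak heavily between 0.1-s-step
overlapping windows).  Hyperparameter search is an exhaustive grid over
the four conv kernel lengths {50, 150, 250} (3⁴ = 81 combinations, ×3
LSTM sizes {50, 100, 150} for LSTM baselines), scored by mean validation
accuracy over the five folds, ties broken toward the lexicographically
smallest tuple.

The whole network stack — convolution via im2col, batch norm, max
pooling, multi-head attention, layer norm, FFN, LSTM, additive attention
pooling, and the Adam loop — is implemented in NumPy with hand-derived
backward passes.  Gradient correctness is pinned by central-difference
tests over every parameter tensor of every variant (float64, tolerance
1e-5 + 1e-3 relative; conv biases sit directly before batch norm, so
their true gradient is ~0 and only the absolute floor applies).
Primitives additionally match brute-force loop oracles to 1e-6.

## Synthetic data: what it emulates and what it does not

`SimConfig` defaults define the study conditions used by the tests and
the reproduction script:

| parameter | default | meaning |
|---|---|---|
| fs | 500 Hz | acquisition rate |
| duration_s | 360 s | recording length (~3000 windows) |
| n_sem_events | 12 | SEM events per recording |
| sem_freq_range | 0.25–0.5 Hz | event frequency (inside the 0.2–0.6 criteria band) |
| sem_amp_range | 30–150 µV | per-channel excursion amplitude (inside 20–200) |
| sem_duration_range | 4–7 s | event length (> 2 s criterion; > 3 s so events yield windows) |
| onset_diff_max_ms | 100 ms | Hl/Hr onset lag (≤ 300 ms criterion) |
| n_saccades | 30 | step-like alert-state deflections (50–200 µV, 20 ms rise) |
| alpha_amp_uv | 10 µV | bursty alpha carrier (8–13 Hz) |
| alpha_attenuation_factor | 0.3 | alpha gain inside SEM intervals |
| eeg_background_sd_uv | 5 µV | pink (1/f) background, band-limited 0.1–30 Hz |
| drift_amp_uv / drift_freq_hz | 30 µV / 0.05 Hz | baseline drift |
| noise_sd_uv | 12 µV | independent white noise per electrode |

Construction: `Hl = +eye + eeg + drift + noise_l`,
`Hr = −eye + eeg + drift + noise_r`; O2 shares the alpha-burst envelope
of the common-mode EEG but has its own background, which reproduces the
high-but-imperfect alpha-energy correlation between HSUM and O2.  SEM
events carry a raised-cosine (Tukey) taper over their first/last 10% so
onset is well defined without step artifacts.  The default onset lag cap
is 100 ms rather than the 300 ms criteria bound: at 0.6 Hz a 300 ms lag
alone drives the Hl/Hr correlation to ≈ −0.43, which no reasonable
phase-opposition threshold would accept; 100 ms keeps every generated
event consistent with all five criteria.  Electrode noise is drawn
independently per channel — identical noise on Hl and Hr would make the
difference trace noise-free and the detection task trivially easy.

Not emulated: blinks and vertical EOG, head-movement artifacts,
electrode drift nonstationarity, subject-specific morphology, and any
realistic between-subject variability.  A model that separates this
simulation perfectly has demonstrated that the pipeline is wired
correctly and that its capacity suffices for the idealized signal
geometry — not that it reaches the published accuracy on recorded data.

## Executable labeling criteria

The visual-marking rules are operationalized in `check_sem_criteria`.
Phase, frequency, amplitude, and onset are measured on a 0.1–1.5 Hz
zero-phase (Butterworth, `sosfiltfilt`) band-passed copy of the epoch —
the slow component a human marker attends to — while the 500 µV artifact
ceiling applies to raw samples.  Specifics, with the reasoning where the
design was open:

* **Dominant frequency**: peak of the zero-padded periodogram of the
  band-passed HEOG (DC bin excluded); must lie in 0.2–0.6 Hz.
* **Fast-transient bound** (part of the frequency verdict): peak of the
  1.5–15 Hz band-passed HEOG must stay below 38 µV, with the first/last
  0.25 s excluded from the peak search (zero-phase filter edge
  transients).  A saccadic step necessarily drives a large fast
  transient, whereas a genuine SEM epoch stays at the noise floor; the
  epoch-level periodogram alone cannot make this distinction because a
  band-passed step can peak inside the SEM band.  The 38 µV threshold
  sits in the gap between the class-conditional distributions measured
  on simulated events (SEM ≤ ~28 µV, saccades ≥ ~51 µV).
* **Phase opposition**: Pearson correlation of Hl and Hr in a narrow
  band around the measured dominant frequency (f/1.6 to 1.6f) must be
  ≤ −0.8.  Measuring in the wide band lets low-frequency 1/f background
  (common mode, hence positively correlated) mask the opposition of
  low-amplitude events.
* **Amplitude**: half the peak-to-peak of HEOG/2, i.e. the per-channel
  excursion amplitude, in 20–200 µV.
* **Onset lag**: cross-correlation peak between the slow components of
  Hl and −Hr, restricted to |lag| ≤ 0.6 s (below half a SEM period, so
  the estimate is unambiguous); must be ≤ 300 ms.  Threshold-crossing
  onset estimates were ~300 ms noisy under realistic backgrounds.
* **Duration**: epoch length must exceed 2 s; shorter epochs fail the
  verdict rather than raising.

On simulated data the validator accepts 100% of ground-truth SEM events
and rejects 100% of saccade and pure-alpha control epochs (measured on
300 events / 400 controls during development; the acceptance suite
re-runs a fresh ~200-event suite).

## Numerical and design choices

* d_model = 64, h = 2, N = 2 defaults; d_ff = 128 (2×d_model); conv
  filter count equals d_model in both layers so the conv output feeds
  the encoder without projection.  Head count must divide d_model.
* Each conv layer has its own pooling factor, default (1, 4): a single
  pool-4 max pooling after the second conv layer (encoder sequence
  length 125 for 500-sample windows).
* Sinusoidal (not learned) positional encoding; post-norm Add & Norm as
  written; layer-norm ε = 1e-5; batch-norm momentum 0.99; no dropout
  inside the encoder (dropout 0.5 in the classifier head only).
* Preprocessing runs on the continuous recording before windowing
  (avoids per-window filter edge artifacts); windows are then decimated
  1500 → 500 by keeping every third sample (signals are band-limited to
  30 Hz, far below the new Nyquist of ~83 Hz).
* Even-window (10-sample) sliding median uses the mean of the two
  central order statistics and reflect padding; DWT baseline removal
  subtracts the level-10 Daubechies-2 approximation under symmetric
  extension (approximation band edge ≈ fs/2¹¹ ≈ 0.24 Hz).
* Alpha-band energy curves: complex Morlet (`cmor1.5-1.0`) CWT sampled
  every 0.25 Hz over 6–14 Hz; the curve is the mean coefficient
  magnitude over frequency.  Per-window correlations beyond 2 SD of
  their mean are removed in a single pass.
* Confusion metrics use argmax (0.5) thresholding; aggregate SDs default
  to the population convention (ddof=0), which is what the published
  per-subject table prints; sample SD is available via ``ddof=1``.
* The baseline CNN-LSTM uses a single LSTM layer on the conv-module
  output followed by global average pooling; CNN-LSTM-Attention replaces
  the pooling with additive (Bahdanau-style) attention.  The
  Transformer-only ablation replaces the conv module with a
  position-wise linear projection and the same total pooling.

## Problem sizes in the test and reproduction runs

The end-to-end recovery experiment trains the scaled-down configuration
(d_model 32, d_ff 64, kernels 25, pools (4, 2), 8 epochs, batch 128) on
one simulated recording (~2800 windows, ~11% SEM prevalence, chronological
70/30 split) for PMMCT and its two structural ablations, three seeds
each.  These sizes are the package's own choice of a desk-scale
experiment; the architecture defaults above remain the full-size ones.
Under these conditions PMMCT reaches a median test F1 of ~1.0 and beats
both the CNN-only and the Transformer-only ablation.  On simulated data
the Transformer-only variant outperforms CNN-only — the reverse of the
ordering reported on recorded signals — because the idealized ocular
waveform is recoverable from raw samples without local feature
extraction; the directional claim verified here is only that the full
model beats both.

## Known limitations

* The published headline numbers (99.89% accuracy / 99.35% F1 on ten
  subjects) are properties of the authors' recordings; this package
  reproduces the published metric arithmetic exactly and the full
  method end to end on simulation, not those numbers.
* No EDF+ annotations, no NeuroScan .cnt reader; EDF support assumes
  whole-second recordings and integer sampling rates.
* Training is single-threaded NumPy: desk-scale by design.  Grid search
  over all 81 combinations with full CV is supported but slow; the test
  suite exercises restricted grids.
* The criteria validator assists but does not replace expert marking on
  real data; its thresholds were set on simulated class-conditional
  distributions.
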