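# Methods

This note documents the models, numerical conventions and design choices
behind `ecgbeat`, in the order the pipeline runs.

## Synthetic ECG generator

Each beat is a sum of five Gaussians (P wave, Q dip, R spike, S dip,
T wave) sampled over a fixed span of −0.35 s … +0.45 s around the R
sample. Class-conditional morphology follows clinical archetypes far
enough for separability, not physiology: V beats are wide (0.16 s QRS),
tall (1.5 mV) with absent P and inverted T; S beats have a reduced P wave
and — in the rhythm generator — a preceding RR interval shortened to 65%
(prematurity); F interpolates N and V; Q is a low-amplitude (0.5 mV),
narrow, degenerate complex. Beat times accumulate RR draws from
N(`rr_mean`, `rr_jitter_sd`) truncated away from the refractory zone;
`rr_mean` defaults to 0.8 s, inside the 0.6–1.0 s band of normal adult
inter-beat intervals. The first beat is placed at t = 1 s so its full
morphology window exists, and generation stops early enough that the last
T wave fits. Additive components — Gaussian high-frequency noise and a
sinusoidal baseline (< 0.5 Hz) — are stored separately, so
`decompose_record` recovers them exactly and `signal = clean + noise +
baseline` holds to the last bit.

What the generator does *not* emulate: motion artifacts, electrode pops,
non-stationary rhythms (AF), pathological morphology families beyond the
five archetypes, and inter-patient variability. Tests passing on this
family therefore demonstrate pipeline correctness (bookkeeping,
identities, detector logic, learnability) — not clinical accuracy on real
recordings.

The classifier tests additionally use `make_separable_dataset`: for
morphology-style inputs, the z-scored class templates plus Gaussian noise
(sd 0.15 against a ~1 mV QRS); for RR-style inputs, five 9-dimensional
centroids encoding the classes' RR dynamics (premature beats with
compensatory pauses of different depth) plus noise of sd 0.12,
corresponding to tens of milliseconds of RR measurement jitter. Both
noise levels were fixed once as realistic values.

## Signal conditioning

The chain is fixed: **resample → denoise → baseline removal → z-score**.

* **Resampling** is Fourier (band-limited) via `scipy.signal.resample`,
  output length `round(n·fs_out/fs_in)`; 130 Hz source streams are
  brought to the 360 Hz model rate.
* **Denoising** is VisuShrink: db8 wavelet, up to 10 decomposition
  levels, noise scale `σ̂ = median(|D1|)/0.6745`, universal threshold
  `σ̂·√(2 ln N)` soft-applied to *all* detail levels (the single-
  threshold-from-D1 reading; a per-level threshold is the other
  defensible reading). If the signal is too short for 10 levels the
  depth is clamped with a logged warning — short stream windows must not
  fail.
* **Baseline removal** subtracts the trend produced by a 71-sample then
  215-sample median cascade (despike first, then extract the slow
  trend; ~0.2 s and ~0.6 s at 360 Hz). Median filters use reflect
  padding — zero padding would bias the trend at the record ends. The
  corrected signal is defined as `x − trend`, so the decomposition
  re-sums to the input at float rounding (≤1e-15 relative).
* **Z-score** uses the population (n-denominator) standard deviation; a
  constant signal is rejected rather than silently zeroed.

## R-peak detection and correction

Pan–Tompkins in its classic stages: 5–15 Hz Butterworth band-pass
(zero-phase `filtfilt`, so no group-delay bookkeeping), five-point
derivative, squaring, 150 ms centred moving-window integration, then
adaptive dual-threshold picking with a 200 ms refractory period. The
signal/noise levels follow the standard recursions (SPKI/NPKI with 1/8
update, threshold `NPKI + 0.25·(SPKI − NPKI)`), seeded from the first
two seconds. Search-back runs whenever the gap since the last accepted
beat exceeds 1.66× the running 8-beat RR average — checked both when a
candidate is rejected and when a new beat is accepted — and retries the
strongest rejected candidate at half threshold. Detections are finally
pinned to the band-passed extremum within ±100 ms. A flat signal yields
an empty peak set, not an error.

Correction (`correct_rpeaks`) replaces each index with the signal argmax
in a ±20-sample window (~55 ms at 360 Hz). Ties resolve to the earliest
sample (deterministic, order-stable); if two corrected peaks collide or
violate the refractory spacing, the earlier one wins, keeping RR
intervals positive.

## Per-beat features

For peak times `t_i` and intervals `rr[i] = t[i+1] − t[i]`, beat `j`
has `RR0 = rr[j-1]` (its coupling interval — short for a premature
beat), `RR-1 = rr[j-2]`, `RR+1 = rr[j]`, and rolling statistics over the
42 intervals preceding `RR0`. The nine features are the three intervals,
the three ratios to `avgRR`, the two ratios to `RR0`, and
`tRR0 = (RR0 − avgRR)/stddevRR`. A beat is retained only with a previous
beat, a next beat and a full 42-interval history, so `n` beats yield
`n − 44` rows; the retention ledger (`n_retained` of `n_total`) is
carried on every feature matrix. `tRR0` is defined as 0 when
`stddevRR < 1e-9` s: on a perfectly regular rhythm the SD of 42
bit-identical floats computes to ~1e-17, not 0, and would otherwise
amplify to ±1.

Morphology rows are the 181 samples `X[r′−90 … r′+90]` (500 ms at
360 Hz); windows that leave the record are dropped and counted. Wavelet
rows are the level-1 db8 approximation coefficients of each segment
(98 values), zero-padded to a fixed 100 — matching the sequence length
the LSTM-FCN consumes; the wavelet family/level for *features* is a
package default, deliberately distinct from the denoiser's 10-level
setting. Morphology and wavelet retention are identical by construction.

Two conventions worth flagging:

* The feature DWT (`dwt_decompose`/`dwt_reconstruct`) uses **zero**
  signal extension. This keeps the analysis operator orthonormal, so
  energy is conserved exactly (Parseval) *and* reconstruction is exact,
  with band lengths `floor((n + 15)/2)` for db8. The cost is that a
  constant signal has nonzero detail coefficients at the boundary (the
  zero extension is a step); vanishing moments hold in the interior.
  The denoiser keeps symmetric extension, where boundary behaviour
  matters more than orthonormality.
* On the classification path (training and inference alike),
  morphology/wavelet model inputs are standardized **per beat**
  (`standardize_rows`). The record-level z-score is affine with a scale
  that depends on the analysis-window length; per-beat standardization
  makes model inputs invariant to that scale, which is what lets
  streamed windows and whole-record batch processing agree beat for
  beat. It is also common practice for inter-record robustness.

## Architectures and training

Three declarative architectures, parameter-countable in closed form:

| | layers | params |
|---|---|---|
| LSTM-Sequential | LSTM(256) → Dense(128, tanh) → Dense(5, softmax) on (9, 1) | 264,192 + 32,896 + 645 |
| Bi-LSTM | BiLSTM(256) → Dense(256, tanh) → Dense(5, softmax) | 528,384 + 131,328 + 1,285 |
| LSTM-FCN | LSTM(8)+Dropout(0.8) ∥ Permute → [Conv1D(128,8) → BN → ReLU → Conv1D(256,5) → BN → ReLU → Conv1D(128,3) → BN → ReLU] → GAP; concat → Dense(5, softmax) on (100, 1) | 320 + 102,528 + 512 + 164,096 + 1,024 + 98,432 + 512 + 685 |

Counting conventions: LSTM `4·(u·(u+d)+u)` (single bias), bidirectional
2×, Conv1D `c·k·f + f`, BatchNorm `4·c` including the two running
statistics (counted, not trained). A 512-unit LSTM-Sequential variant
uses the same builder. In the LSTM-FCN the convolutional branch sees the
*permuted* input — the 100 time steps become 100 channels of a length-1
sequence — which is what makes the first convolution 100·8·128+128
parameters; the LSTM branch sees the raw (100, 1) sequence.

The backend (`ecgbeat.nn`) is a plain numpy implementation with exact
gradients (verified against central differences at 1e-6): Keras-layout
LSTM with gate order i,f,g,o and forget-bias 1, orthogonal recurrent
init, Glorot/He-uniform kernel inits, 'same' conv padding (left
`(k−1)//2`), BatchNorm over batch×time per channel (momentum 0.99,
eps 1e-3), inverted dropout. Softmax is folded into the cross-entropy
loss for numerical stability; `predict_proba` applies it explicitly.

Training: stratified 70/30 split at a fixed seed (a warning and
unstratified fallback if a class has a single member; stratification
matters because the Q class can be tiny), one-hot targets, categorical
cross-entropy, Adam at 1e-3, batch 256, up to 50 epochs, optional
early-stopping patience on the held-out loss. The split is beat-wise,
not record-wise. No class rebalancing. All randomness flows from the
config seed, so runs are bit-reproducible.

Evaluation: accuracy = trace/total of the 5×5 confusion matrix;
precision/recall/F1 are support-weighted (macro values are reported
alongside); per-class accuracy is the per-class recall — the only
per-class scalar a single confusion matrix defines. Weighted recall
equals accuracy identically, a property the tests assert.

Saved models are a backend-independent JSON architecture spec plus an
array container of weights; the export metadata fixes the streaming
batch size at 1.

## Streaming

A session buffers source-rate samples and re-analyses every 2 s of new
data once 10 s are available. The analysis window is *expanding* — the
whole buffer is reprocessed — rather than a fixed sliding window: the
conditioning chain contains global operations (Fourier resampling,
VisuShrink's N-dependent threshold, z-score), so an expanding window
makes each beat's features converge to exactly what the offline pipeline
computes, and per-beat standardization (above) removes the remaining
scale dependence. Beats within 0.5 s of the stream head are deferred so
the right morphology margin and the next RR interval exist; in RRI mode
the 42-interval warm-up and the next-beat requirement delay emission
accordingly. Each emitted beat carries the feature+forward wall time
(`inference_s`) and the whole pass's wall time (`end_to_end_s`); the
real-time metric is the fraction of beats with `end_to_end_s` under
0.6 s — the shortest normal inter-beat interval. Reprocessing cost grows
with the buffer, which is acceptable at the record lengths tested
(minutes); a production deployment would checkpoint and trim the buffer.

The REST service (`stream.serve`, stdlib HTTP) exposes
`POST /session`, `POST /session/{id}/chunk`, `GET /session/{id}/stats`
and `GET /health`; sessions are isolated behind a lock, and chunk
payloads use the documented JSON dialect
(`{"timestamp_ms", "fs", "samples"}`, responses with `beat_index`,
`r_peak_time_s`, `label`, `confidence`, `inference_ms`).

## Problem sizes used by the tests and acceptance script

Detector quality runs on ~98 s records (≥120 beats) at 360 Hz, clean and
with high-frequency noise at 5% of the QRS amplitude. Scaled-down
learning uses 5,000-beat separable sets, 10 epochs, batch 256.
The streaming model is an LSTM-FCN trained for 60 epochs on wavelet
features of four 10-minute synthetic records (~3,000 beats); streaming
equivalence uses a 5-minute 130 Hz record replayed at 0.5 s, 1 s and 5 s
chunks against the batch pipeline. Transform identities use 500 random
signals each. The full-database retention checks (44 records, 97,806 RRI
rows, 100,708 morphology/wavelet rows) require a local MIT-BIH copy and
live in an integration test that skips without one.

## Known limitations

* The WFDB reader covers format-16 single-file records and MIT-format
  annotations — enough for round trips and converted databases, not the
  full format zoo (212-packed mitdb files need prior conversion).
* Pan–Tompkins parameters are the classic ones; no detector retuning per
  sampling rate beyond the sample-count conversions.
* The streaming session holds the entire record in memory and reprocesses
  it per hop; latency stays well under the 0.6 s bound at the tested
  lengths, but unbounded sessions would need buffer trimming.
* Synthetic-data results bound pipeline correctness, not clinical
  performance; headline accuracies on real arrhythmia databases require
  the full dataset and longer training than the test suite performs.
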