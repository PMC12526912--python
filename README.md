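# ecgbeat

Real-time heartbeat classification for single-lead ECG streams.

Wearable chest-strap sensors (Polar-H10 class, 130 Hz) can stream raw ECG
continuously, but turning that stream into clinically meaningful per-beat
labels — the five AAMI classes **N** (normal), **S** (supraventricular
ectopic), **V** (ventricular ectopic), **F** (fusion), **Q** (unknown) —
requires a full pipeline: signal conditioning, QRS detection, per-beat
feature extraction, a trained classifier, and latency accounting tight
enough to keep up with the heart (a beat every 0.6–1.0 s). `ecgbeat`
implements that pipeline as a tested Python library plus a thin CLI, with
a synthetic-ECG generator so every stage is verifiable without any
external dataset.

## What is inside

| Module | Role |
|---|---|
| `ecgbeat.synthdata` | Synthetic P-QRS-T records with ground-truth R-peaks, per-class morphology, HF noise and baseline wander |
| `ecgbeat.io_records` | Minimal WFDB reader/writer, MIT-BIH→AAMI symbol map, JSON stream-chunk dialect |
| `ecgbeat.preprocess` | Fourier resampling to 360 Hz, VisuShrink (db8, soft) denoising, 71/215 double-median baseline removal, z-score |
| `ecgbeat.rpeak` | Pan–Tompkins QRS detection, local-argmax R-peak correction (±20 samples) |
| `ecgbeat.features` | 9 RR-interval features over a 42-beat rolling window; 181-sample morphology segments; level-1 db8 approximation-coefficient (wavelet) features |
| `ecgbeat.models` | LSTM-Sequential, Bi-LSTM and LSTM-FCN architectures with closed-form parameter counts, training (Adam 1e-3, batch 256, stratified 70/30) and evaluation |
| `ecgbeat.stream` | Chunked-JSON streaming sessions, batch-equivalent windowed inference, REST service, 0.6 s real-time compliance metric |

The classifiers run on a small exact numpy backend (`ecgbeat.nn`) with
full forward/backward passes; the declarative architecture specs are
independently countable, e.g. an LSTM layer holds `4·(u·(u+d)+u)`
parameters, so `parameter_count(build_lstm_sequential())` = 264,192 +
32,896 + 645 = 297,733, and the instantiated network reports the same
total.

Key per-beat features, for R-peak times `t_i` and `rr_i = t_{i+1} − t_i`:

```
RR0 = rr[j-1]        RR-1 = rr[j-2]        RR+1 = rr[j]
avgRR, stddevRR      mean / population SD of the 42 preceding intervals
tRR0 = (RR0 − avgRR) / stddevRR
```

plus the ratios RR0/avgRR, RR−1/avgRR, RR+1/avgRR, RR−1/RR0, RR+1/RR0 —
nine features per beat. Morphology segments are
`X[r′−90 … r′+90]` around the corrected peak
`r′ = argmax_{|k−r|≤20} X_k`; wavelet features keep the highest-level
approximation coefficients `A_L` of each segment.

## Worked example

```python
import numpy as np
from ecgbeat import (SyntheticRecordConfig, generate_record, preprocess_signal,
                     pan_tompkins, correct_rpeaks, segment_beats,
                     standardize_rows, wavelet_feature_matrix,
                     build_lstm_fcn, train, evaluate, TrainConfig)
from ecgbeat.features import labels_for_peaks
from ecgbeat.rpeak import RPeakSet

cfg = SyntheticRecordConfig(duration=600, fs=360, rr_mean=0.8,
                            rr_jitter_sd=0.05,
                            class_mix=(0.5, 0.15, 0.15, 0.1, 0.1),
                            hf_noise_sd=0.02, baseline_amplitude=0.15, seed=11)
rec = generate_record(cfg)
x = preprocess_signal(rec.signal, rec.fs)            # 360 Hz, denoised, flat, z-scored
peaks = correct_rpeaks(x, pan_tompkins(x, 360.0))
labels, ok = labels_for_peaks(peaks, rec.true_rpeaks, rec.true_labels)
keep = np.where(ok)[0]
segs = segment_beats(x, RPeakSet(peaks.indices[keep], 360.0), [labels[i] for i in keep])
segs.X = standardize_rows(segs.X)
wf = wavelet_feature_matrix(segs)                    # (n_beats, 100)
print(f"{wf.n_retained}/{wf.n_total} beats retained")

model = train(build_lstm_fcn(100), wf, TrainConfig(epochs=30, seed=3))
print(f"test accuracy {evaluate(model).accuracy:.3f}")
```

Output:

```
786/786 beats retained
test accuracy 0.924
```

786 beats were detected, matched to ground truth and segmented (none
fell close enough to the record ends to lose their 181-sample window).
The held-out 30% split is classified at 92% accuracy after 30 epochs on
a single record's beats; the test suite trains on four records and
reaches 1.00 on this synthetic family.

The same flow is available from the shell:

```bash
ecgbeat synth --duration 300 --fs 130 --rr-mean 0.8 --seed 1 --out rec.npz
ecgbeat stream-sim --record rec.npz --model mymodel --feature-kind wavelet \
    --chunk-ms 1000 --report latency.json
```

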