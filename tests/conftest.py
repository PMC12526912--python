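"""Shared fixtures: synthetic records and a trained wavelet-feature model."""

from __future__ import annotations

import numpy as np
import pytest

from ecgbeat import features, models, preprocess, rpeak, synthdata

MIXED = (0.5, 0.15, 0.15, 0.1, 0.1)


def make_record(duration=60.0, fs=360.0, rr_mean=0.8, jitter=0.0,
                class_mix=(1.0, 0, 0, 0, 0), noise=0.0, baseline=0.0, seed=0):
    cfg = synthdata.SyntheticRecordConfig(
        duration=duration, fs=fs, rr_mean=rr_mean, rr_jitter_sd=jitter,
        class_mix=class_mix, hf_noise_sd=noise, baseline_amplitude=baseline,
        seed=seed)
    return synthdata.generate_record(cfg)


def wavelet_training_set(seeds, duration=600.0):
    """Offline-pipeline wavelet features from synthetic records, labelled
    from ground truth by nearest-peak matching."""
    Xs, labs = [], []
    for sd in seeds:
        rec = make_record(duration=duration, jitter=0.05, class_mix=MIXED,
                          noise=0.02, baseline=0.15, seed=sd)
        x = preprocess.preprocess_signal(rec.signal, rec.fs)
        pk = rpeak.correct_rpeaks(x, rpeak.pan_tompkins(x, 360.0))
        ls, mask = features.labels_for_peaks(
            pk, rec.true_rpeaks, rec.true_labels, truth_fs=rec.fs)
        keep = np.where(mask)[0]
        pk2 = rpeak.RPeakSet(pk.indices[keep], pk.fs, pk.source)
        segs = features.segment_beats(x, pk2, [ls[i] for i in keep])
        segs.X = features.standardize_rows(segs.X)   # per-beat, as at inference
        wf = features.wavelet_feature_matrix(segs)
        Xs.append(wf.X)
        labs += wf.labels
    return np.vstack(Xs), labs


@pytest.fixture(scope="session")
def wavelet_model():
    """LSTM-FCN trained on wavelet features of synthetic records; used by
    the streaming tests (the deployed configuration is wavelet features)."""
    X, labs = wavelet_training_set([11, 21, 31, 41])
    return models.train(models.build_lstm_fcn(100), (X, labs),
                        models.TrainConfig(epochs=60, seed=3))
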