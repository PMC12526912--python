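"""Feature extractors: RR statistics, segmentation, wavelet coefficients."""

import numpy as np
import pytest

from ecgbeat.features import (
    RRI_WINDOW,
    FeatureError,
    compute_rr_intervals,
    dwt_decompose,
    dwt_reconstruct,
    labels_for_peaks,
    resample_rows,
    rolling_rr_stats,
    rri_feature_matrix,
    segment_beats,
    wavelet_feature_matrix,
)
from ecgbeat.rpeak import RPeakSet

from conftest import make_record


def brute_force_rri_rows(indices, fs, labels, window=RRI_WINDOW):
    """Independent per-beat reimplementation of the 9 temporal features."""
    t = np.asarray(indices) / fs
    rr = np.diff(t)
    rows, kept = [], []
    for j in range(len(indices)):
        i0 = j - 1
        if i0 - 1 < 0 or i0 + 1 >= len(rr) or i0 - window < 0:
            continue
        hist = rr[i0 - window:i0]
        a, s = hist.mean(), hist.std()
        rr0, rrp, rrn = rr[i0], rr[i0 - 1], rr[i0 + 1]
        rows.append([rr0, rrp, rrn, rr0 / a, rrp / a, rrn / a,
                     rrp / rr0, rrn / rr0,
                     0.0 if s < 1e-9 else (rr0 - a) / s])
        kept.append(labels[j])
    return np.array(rows), kept


# ---------------------------------------------------------------------------
# RR intervals and rolling statistics
# ---------------------------------------------------------------------------

def test_rr_interval_examples():
    assert np.allclose(
        compute_rr_intervals(RPeakSet(np.array([0, 360, 720]), 360.0)),
        [1.0, 1.0])
    assert np.allclose(
        compute_rr_intervals(RPeakSet(np.array([0, 270, 720]), 360.0)),
        [0.75, 1.25])


def test_rr_requires_two_peaks():
    with pytest.raises(FeatureError):
        compute_rr_intervals(RPeakSet(np.array([5]), 360.0))


def test_rolling_stats_constant():
    avg, sd, valid = rolling_rr_stats(np.full(60, 0.8))
    assert np.allclose(avg[valid], 0.8) and np.allclose(sd[valid], 0.0)
    assert not valid[:RRI_WINDOW].any() and valid[RRI_WINDOW:].all()


def test_rolling_stats_alternating_closed_form():
    rr = np.tile([0.6, 1.0], 30)
    avg, sd, valid = rolling_rr_stats(rr)
    # any 42 consecutive values hold 21 of each: mean .8, pop sd .2
    assert np.allclose(avg[valid], 0.8)
    assert np.allclose(sd[valid], 0.2)


def test_rolling_stats_short_history_all_invalid():
    _, _, valid = rolling_rr_stats(np.full(41, 0.8))
    assert not valid.any()


# ---------------------------------------------------------------------------
# RRI feature matrix
# ---------------------------------------------------------------------------

def test_periodic_record_gives_unit_ratios():
    idx = np.arange(100) * 288           # exactly 0.8 s at 360 Hz
    peaks = RPeakSet(idx, 360.0, "annotation")
    fm = rri_feature_matrix(peaks, ["N"] * 100)
    assert fm.n_total == 100
    assert fm.n_retained == 100 - (RRI_WINDOW + 2)
    assert np.allclose(fm.X[:, 3:8], 1.0)     # all ratio features
    assert np.allclose(fm.X[:, 8], 0.0)       # t_rr0 on a regular rhythm


@pytest.mark.parametrize("seed", range(20))
def test_rri_matrix_matches_brute_force(seed):
    rec = make_record(duration=90, jitter=0.06, seed=seed,
                      class_mix=(0.6, 0.2, 0.1, 0.05, 0.05))
    peaks = RPeakSet(rec.true_rpeaks, rec.fs, "annotation")
    fm = rri_feature_matrix(peaks, rec.true_labels)
    expected, kept = brute_force_rri_rows(rec.true_rpeaks, rec.fs, rec.true_labels)
    assert fm.X.shape == expected.shape
    assert np.allclose(fm.X, expected, atol=1e-12)
    assert fm.labels == kept


def test_rri_ratios_scale_invariant():
    rng = np.random.default_rng(3)
    rr = 0.7 + 0.1 * rng.random(80)
    idx = np.concatenate([[0], np.cumsum(np.round(rr * 360))]).astype(int)
    a = rri_feature_matrix(RPeakSet(idx, 360.0), ["N"] * len(idx))
    b = rri_feature_matrix(RPeakSet(idx * 2, 360.0), ["N"] * len(idx))
    assert np.allclose(a.X[:, 3:], b.X[:, 3:], atol=1e-9)


# ---------------------------------------------------------------------------
# morphology segmentation
# ---------------------------------------------------------------------------

def test_segment_index_arithmetic():
    x = np.arange(2000, dtype=float)
    fm = segment_beats(x, RPeakSet(np.array([1000]), 360.0), ["N"])
    assert fm.X.shape == (1, 181)
    assert fm.X[0, 0] == 910 and fm.X[0, -1] == 1090


def test_segment_boundary_drop_and_accounting():
    x = np.zeros(1000)
    peaks = RPeakSet(np.array([50, 500, 950]), 360.0)
    fm = segment_beats(x, peaks, ["N", "V", "N"])
    assert fm.n_total == 3 and fm.n_retained == 1
    assert fm.labels == ["V"]


# ---------------------------------------------------------------------------
# DWT
# ---------------------------------------------------------------------------

def test_dwt_constant_details_vanish():
    # vanishing moments: interior detail coefficients of a constant are 0
    # (the zero signal extension excites only the boundary coefficients,
    # whose reach grows with level — so check the single-level band)
    out = dwt_decompose(np.full(256, 3.0), "db8", 1)
    d1 = out["D"][0]
    assert np.max(np.abs(d1[8:-8])) < 1e-10
    assert np.max(np.abs(d1)) > 0  # boundary step is real


def test_dwt_a1_length_for_segment():
    out = dwt_decompose(np.random.default_rng(0).standard_normal(181), "db8", 1)
    assert len(out["A"]) == (181 + 16 - 1) // 2   # filter length 16 -> 98


def test_dwt_parseval_energy():
    x = np.random.default_rng(1).standard_normal(512)
    out = dwt_decompose(x, "db8", 4)
    energy = np.sum(out["A"] ** 2) + sum(np.sum(d ** 2) for d in out["D"])
    assert abs(energy - np.sum(x ** 2)) < 1e-8


@pytest.mark.parametrize("seed", range(10))
def test_dwt_round_trip(seed):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(int(rng.integers(64, 700)))
    out = dwt_decompose(x, "db8", int(rng.integers(1, 3)))
    assert np.max(np.abs(dwt_reconstruct(out) - x)) < 1e-8


def test_dwt_zero_coeffs_give_zero_signal():
    out = dwt_decompose(np.zeros(200), "db8", 2)
    assert not dwt_reconstruct(out).any()


def test_dwt_zeroing_details_smooths():
    rng = np.random.default_rng(2)
    x = np.sin(np.arange(512) / 20.0) + 0.3 * rng.standard_normal(512)
    out = dwt_decompose(x, "db8", 3)
    out["D"] = [np.zeros_like(d) for d in out["D"]]
    smooth = dwt_reconstruct(out)
    assert np.var(np.diff(smooth)) < np.var(np.diff(x))


def test_dwt_infeasible_level_rejected():
    with pytest.raises(FeatureError):
        dwt_decompose(np.zeros(32), "db8", 10)


# ---------------------------------------------------------------------------
# wavelet feature matrix
# ---------------------------------------------------------------------------

def test_wavelet_matrix_retention_matches_morphology():
    rec = make_record(duration=60, jitter=0.05, seed=5,
                      class_mix=(0.6, 0.2, 0.1, 0.05, 0.05))
    peaks = RPeakSet(rec.true_rpeaks, rec.fs, "annotation")
    segs = segment_beats(rec.signal, peaks, rec.true_labels)
    wf = wavelet_feature_matrix(segs)
    assert wf.n_retained == segs.n_retained
    assert wf.n_total == segs.n_total
    assert wf.labels == segs.labels
    assert wf.X.shape == (segs.n_retained, 100)


def test_wavelet_matrix_constant_segment():
    segs = segment_beats(np.full(2000, 2.0), RPeakSet(np.array([1000]), 360.0), ["N"])
    wf = wavelet_feature_matrix(segs)
    a = wf.X[0, 8:90]   # interior approximation coefficients
    assert np.allclose(a, a[0]) and a[0] != 0          # constant * filter gain
    assert np.isclose(a[0], 2.0 * np.sqrt(2))          # db gain sqrt(2) per level
    assert not wf.X[0, 98:].any()                       # zero padding


def test_resample_rows_bridges_lengths():
    X = np.vstack([np.linspace(0, 1, 181)] * 3)
    out = resample_rows(X, 100)
    assert out.shape == (3, 100)
    assert np.allclose(out[0, [0, -1]], [0.0, 1.0])


def test_labels_for_peaks_matching():
    truth_idx = np.array([360, 720, 1080])
    peaks = RPeakSet(np.array([361, 725, 2000]), 360.0)
    labs, mask = labels_for_peaks(peaks, truth_idx, ["N", "V", "S"])
    assert labs == ["N", "V", None]
    assert mask.tolist() == [True, True, False]
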