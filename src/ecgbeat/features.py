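"""Per-beat feature extraction: RR-interval, morphology, wavelet.

Three representations share one bookkeeping convention: every extractor
reports how many of the annotated/detected beats survived its validity
rules (``n_retained`` of ``n_total``), because each scheme discards
different boundary beats — the RR scheme needs a 42-interval history plus
a previous and a next beat, while the morphology/wavelet schemes only need
the segment window to fit inside the record (hence identical retention for
those two).

Conventions for beat ``j`` (0-based over the R-peak list, with
``rr[i] = t[i+1] - t[i]``):

* ``RR0   = rr[j-1]`` — the beat's own coupling interval (short for a
  premature beat);
* ``RR-1  = rr[j-2]``, ``RR+1 = rr[j]``;
* ``avgRR``/``stddevRR`` — mean and population SD of the 42 intervals
  preceding ``RR0`` (``rr[j-43 … j-2]``);
* ``tRR0 = (RR0 - avgRR)/stddevRR``, defined as 0 for a perfectly regular
  history (``stddevRR`` below 1 ns — exact zero is unreliable in floating
  point when 42 identical intervals are averaged).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from ecgbeat.rpeak import RPeakSet

RRI_WINDOW = 42
RRI_FEATURE_NAMES = (
    "rr0", "rr_prev", "rr_next",
    "rr0_over_avg", "rr_prev_over_avg", "rr_next_over_avg",
    "rr_prev_over_rr0", "rr_next_over_rr0", "t_rr0",
)


class FeatureError(ValueError):
    """Invalid input to a feature extractor."""


@dataclass
class FeatureMatrix:
    """Aligned per-beat feature rows with retention accounting."""

    X: np.ndarray                  # (n_retained, n_features)
    labels: list[str]
    feature_kind: str              # rri | morphology | wavelet
    n_retained: int
    n_total: int
    beat_indices: np.ndarray = None    # index into the source peak list
    r_indices: np.ndarray = None       # corrected R sample per row
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_retained > self.n_total:
            raise FeatureError("n_retained cannot exceed n_total")
        if len(self.X) != self.n_retained or len(self.labels) != self.n_retained:
            raise FeatureError("rows/labels must match n_retained")


def compute_rr_intervals(rpeaks: RPeakSet) -> np.ndarray:
    """Consecutive R-peak spacings in seconds; length ``n_peaks - 1``."""
    if len(rpeaks) < 2:
        raise FeatureError("need at least 2 R-peaks for RR intervals")
    rr = np.diff(rpeaks.indices) / rpeaks.fs
    return rr


def rolling_rr_stats(
    rr: np.ndarray, window: int = RRI_WINDOW
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rolling mean / population SD of the ``window`` preceding intervals.

    Position ``i`` summarizes ``rr[i-window … i-1]``; positions with
    insufficient history carry NaN and are flagged invalid.  Returns
    ``(avg, sd, valid)``.
    """
    rr = np.asarray(rr, dtype=float)
    n = len(rr)
    avg = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for i in range(window, n):
        hist = rr[i - window:i]
        avg[i] = hist.mean()
        sd[i] = hist.std()
        valid[i] = True
    return avg, sd, valid


def rri_feature_matrix(
    rpeaks: RPeakSet,
    labels: list[str] | None = None,
    window: int = RRI_WINDOW,
) -> FeatureMatrix:
    """The 9 temporal features per beat, with warm-up/boundary beats dropped.

    A beat is retained when it has a previous beat, a next beat and a full
    ``window`` of preceding intervals; for ``n`` beats that is
    ``n - (window + 2)`` rows.
    """
    n = len(rpeaks)
    if labels is None:
        labels = ["?"] * n          # unlabeled inference-time extraction
    if len(labels) != n:
        raise FeatureError("labels must align with peaks")
    rr = compute_rr_intervals(rpeaks)
    avg, sd, valid = rolling_rr_stats(rr, window)

    rows, kept_labels, beat_idx = [], [], []
    for j in range(n):
        i0 = j - 1              # index of RR0 in rr
        if i0 - 1 < 0 or i0 + 1 >= len(rr) or not valid[i0]:
            continue
        rr0, rrp, rrn = rr[i0], rr[i0 - 1], rr[i0 + 1]
        a, s = avg[i0], sd[i0]
        t_rr0 = 0.0 if s < 1e-9 else (rr0 - a) / s
        rows.append([
            rr0, rrp, rrn,
            rr0 / a, rrp / a, rrn / a,
            rrp / rr0, rrn / rr0,
            t_rr0,
        ])
        kept_labels.append(labels[j])
        beat_idx.append(j)

    X = np.asarray(rows, dtype=float).reshape(len(rows), len(RRI_FEATURE_NAMES))
    return FeatureMatrix(
        X=X, labels=kept_labels, feature_kind="rri",
        n_retained=len(rows), n_total=n,
        beat_indices=np.asarray(beat_idx, dtype=int),
        r_indices=rpeaks.indices[np.asarray(beat_idx, dtype=int)] if rows else np.array([], dtype=int),
        meta={"window": window, "feature_names": RRI_FEATURE_NAMES},
    )


def segment_beats(
    signal: np.ndarray,
    rpeaks: RPeakSet,
    labels: list[str] | None = None,
    w_left: int = 90,
    w_right: int = 90,
) -> FeatureMatrix:
    """Fixed-length morphology windows around each corrected R-peak.

    Each row spans ``[r - w_left, r + w_right]`` inclusive (181 samples at
    the defaults, a 500 ms window at 360 Hz); beats whose window leaves the
    record are dropped and counted.
    """
    x = np.asarray(signal, dtype=float)
    n = len(rpeaks)
    if labels is None:
        labels = ["?"] * n
    if len(labels) != n:
        raise FeatureError("labels must align with peaks")
    rows, kept_labels, beat_idx, r_idx = [], [], [], []
    for j, r in enumerate(rpeaks.indices):
        lo, hi = r - w_left, r + w_right + 1
        if lo < 0 or hi > len(x):
            continue
        rows.append(x[lo:hi])
        kept_labels.append(labels[j])
        beat_idx.append(j)
        r_idx.append(r)
    X = (np.vstack(rows) if rows
         else np.empty((0, w_left + w_right + 1)))
    return FeatureMatrix(
        X=X, labels=kept_labels, feature_kind="morphology",
        n_retained=len(rows), n_total=n,
        beat_indices=np.asarray(beat_idx, dtype=int),
        r_indices=np.asarray(r_idx, dtype=int),
        meta={"w_left": w_left, "w_right": w_right},
    )


# ---------------------------------------------------------------------------
# Discrete wavelet transform
# ---------------------------------------------------------------------------

def dwt_decompose(x: np.ndarray, wavelet: str = "db8", level: int = 1) -> dict:
    """Multilevel DWT: approximation ``A_L`` plus details ``D_L … D_1``.

    Zero signal extension keeps the analysis operator orthonormal, so the
    transform conserves energy exactly (Parseval) and still reconstructs
    perfectly; each coefficient band has length ``floor((n + L_f - 1)/2)``
    for filter length ``L_f``.
    """
    x = np.asarray(x, dtype=float)
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(len(x), wav.dec_len)
    if level < 1 or level > max_level:
        raise FeatureError(
            f"level {level} infeasible for length {len(x)} with {wavelet} "
            f"(max {max_level})")
    coeffs = pywt.wavedec(x, wav, level=level, mode="zero")
    return {
        "A": coeffs[0],
        "D": coeffs[1:],          # ordered D_L … D_1
        "wavelet": wavelet,
        "level": level,
        "length": len(x),
    }


def dwt_reconstruct(coeffs: dict) -> np.ndarray:
    """Inverse DWT; exact round trip up to length-parity trimming."""
    try:
        parts = [coeffs["A"], *coeffs["D"]]
        wavelet = coeffs["wavelet"]
    except (KeyError, TypeError) as exc:
        raise FeatureError("coefficient dict must come from dwt_decompose") from exc
    lengths = [len(c) for c in parts]
    for a, b in zip(lengths, lengths[1:]):
        if abs(a - b) > max(lengths):
            raise FeatureError("inconsistent coefficient lengths")
    out = pywt.waverec(parts, wavelet, mode="zero")
    n = coeffs.get("length")
    return out[:n] if n is not None else out


def wavelet_feature_matrix(
    segments: FeatureMatrix,
    wavelet: str = "db8",
    level: int = 1,
    feature_length: int = 100,
) -> FeatureMatrix:
    """Highest-level approximation coefficients of each beat segment.

    Retention is identical to the morphology matrix by construction (the
    same segments feed both).  Each coefficient row is zero-padded or
    truncated to ``feature_length`` so the matrix is rectangular.
    """
    if segments.feature_kind != "morphology":
        raise FeatureError("wavelet features are derived from morphology segments")
    rows = []
    for seg in segments.X:
        a = dwt_decompose(seg, wavelet, level)["A"]
        if len(a) >= feature_length:
            rows.append(a[:feature_length])
        else:
            rows.append(np.pad(a, (0, feature_length - len(a))))
    X = np.vstack(rows) if rows else np.empty((0, feature_length))
    return FeatureMatrix(
        X=X, labels=list(segments.labels), feature_kind="wavelet",
        n_retained=segments.n_retained, n_total=segments.n_total,
        beat_indices=segments.beat_indices, r_indices=segments.r_indices,
        meta={"wavelet": wavelet, "level": level,
              "feature_length": feature_length, **segments.meta},
    )


def standardize_rows(X: np.ndarray) -> np.ndarray:
    """Z-score each beat row independently (constant rows become zero).

    Per-beat standardization makes morphology/wavelet model inputs
    invariant to the affine scale of the record-level normalization — in
    streaming, windows of different lengths z-score to slightly different
    scales, and this removes that dependence entirely.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return (X - mean) / sd


def resample_rows(X: np.ndarray, length: int) -> np.ndarray:
    """Linearly resample each row to ``length`` samples (model input bridge)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] == length:
        return X.copy()
    xs = np.linspace(0, X.shape[1] - 1, length)
    base = np.arange(X.shape[1])
    return np.vstack([np.interp(xs, base, row) for row in X])


def labels_for_peaks(
    rpeaks: RPeakSet,
    truth_indices: np.ndarray,
    truth_labels: list[str],
    tolerance_s: float = 0.050,
    truth_fs: float | None = None,
) -> tuple[list[str | None], np.ndarray]:
    """Assign each detected peak the class of the nearest true beat.

    Peaks with no true beat within ``tolerance_s`` get ``None``.  Truth
    indices may live on a different sampling grid (``truth_fs``).
    """
    truth_fs = truth_fs or rpeaks.fs
    truth_t = np.asarray(truth_indices, dtype=float) / truth_fs
    out: list[str | None] = []
    for t in rpeaks.times_s:
        if len(truth_t) == 0:
            out.append(None)
            continue
        k = int(np.argmin(np.abs(truth_t - t)))
        out.append(truth_labels[k] if abs(truth_t[k] - t) <= tolerance_s else None)
    return out, np.asarray([lab is not None for lab in out], dtype=bool)
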