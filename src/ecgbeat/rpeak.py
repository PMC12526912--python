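"""R-peak detection (Pan–Tompkins) and local-argmax correction.

The detector follows the classic stages: 5–15 Hz band-pass, derivative,
squaring, 150 ms moving-window integration, then adaptive dual-threshold
peak picking with a 200 ms refractory period and a search-back pass for
long RR gaps.  Filtering is zero-phase and the integrator is centred, so
detections land on the input sample grid without group-delay bookkeeping;
a final local search on the band-passed signal pins each detection to the
QRS extremum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

REFRACTORY_S = 0.200       # minimum physiological QRS spacing
_BANDPASS_HZ = (5.0, 15.0)
_INTEGRATION_S = 0.150


class RPeakError(ValueError):
    """Invalid input to the R-peak stage."""


@dataclass
class RPeakSet:
    """Strictly increasing R-peak sample indices on a known grid."""

    indices: np.ndarray
    fs: float
    source: str = "pan_tompkins"   # or "annotation"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.fs <= 0:
            raise RPeakError("fs must be positive")
        if len(self.indices) and np.any(np.diff(self.indices) <= 0):
            raise RPeakError("R-peak indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def times_s(self) -> np.ndarray:
        return self.indices / self.fs


def _moving_window_integral(x: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def pan_tompkins(signal: np.ndarray, fs: float) -> RPeakSet:
    """Detect R-peaks; returns indices on the input grid.

    A flat or empty-energy signal yields an empty peak set rather than an
    error — only inputs too short for the filters are rejected.
    """
    x = np.asarray(signal, dtype=float)
    if fs < 100:
        raise RPeakError("pan_tompkins requires fs >= 100 Hz")
    if len(x) < 2 * fs:
        raise RPeakError("need at least 2 s of signal")

    nyq = fs / 2.0
    b, a = sps.butter(2, [_BANDPASS_HZ[0] / nyq, _BANDPASS_HZ[1] / nyq], "band")
    band = sps.filtfilt(b, a, x)
    deriv = np.convolve(band, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    energy = _moving_window_integral(deriv ** 2, max(1, int(round(_INTEGRATION_S * fs))))

    refractory = int(round(REFRACTORY_S * fs))
    if energy.max() <= 0:
        return RPeakSet(np.array([], dtype=int), fs)
    candidates, _ = sps.find_peaks(energy, distance=refractory)
    if len(candidates) == 0:
        return RPeakSet(np.array([], dtype=int), fs)

    # adaptive dual thresholds seeded from the first two seconds
    lead_in = energy[: int(2 * fs)]
    spki = 0.25 * lead_in.max()
    npki = 0.5 * lead_in.mean()
    accepted: list[int] = []
    noise_peaks: list[int] = []
    rr_history: list[float] = []

    def threshold() -> float:
        return npki + 0.25 * (spki - npki)

    def search_back(upto: int) -> None:
        # a long RR gap suggests a missed beat among rejected candidates;
        # retry the strongest one at half threshold
        nonlocal spki
        if not (rr_history and accepted):
            return
        rr_avg = float(np.mean(rr_history))
        if upto - accepted[-1] <= 1.66 * rr_avg:
            return
        back = [q for q in noise_peaks
                if accepted[-1] + refractory <= q <= upto - refractory]
        if back:
            best = max(back, key=lambda q: energy[q])
            if energy[best] > 0.5 * threshold():
                accepted.append(int(best))
                accepted.sort()
                noise_peaks.remove(best)
                spki = 0.25 * energy[best] + 0.75 * spki

    for p in candidates:
        v = energy[p]
        if v > threshold():
            if accepted and p - accepted[-1] < refractory:
                continue
            search_back(int(p))
            accepted.append(int(p))
            accepted.sort()
            spki = 0.125 * v + 0.875 * spki
            if len(accepted) >= 2:
                rr_history.append(accepted[-1] - accepted[-2])
                rr_history[:] = rr_history[-8:]
        else:
            noise_peaks.append(int(p))
            npki = 0.125 * v + 0.875 * npki
            search_back(int(p))

    # pin each detection to the band-passed QRS extremum nearby
    half = int(round(0.10 * fs))
    pinned = []
    for p in accepted:
        lo, hi = max(0, p - half), min(len(x), p + half + 1)
        pinned.append(lo + int(np.argmax(np.abs(band[lo:hi]))))
    pinned = sorted(set(pinned))
    # enforce the refractory period after pinning
    final: list[int] = []
    for p in pinned:
        if final and p - final[-1] < refractory:
            continue
        final.append(p)
    return RPeakSet(np.asarray(final, dtype=int), fs)


def correct_rpeaks(
    signal: np.ndarray, peaks: RPeakSet, w_corr: int = 20
) -> RPeakSet:
    """Refine each peak to the signal argmax in a ±``w_corr`` sample window.

    Ties resolve to the earliest sample; if two corrected peaks collide on
    one sample (or violate the refractory spacing) the earlier original is
    kept, so RR intervals stay positive.
    """
    x = np.asarray(signal, dtype=float)
    if w_corr < 1:
        raise RPeakError("w_corr must be >= 1")
    refractory = int(round(REFRACTORY_S * peaks.fs))
    corrected: list[int] = []
    for r in peaks.indices:
        lo, hi = max(0, r - w_corr), min(len(x), r + w_corr + 1)
        if lo >= hi:
            continue
        new = lo + int(np.argmax(x[lo:hi]))  # argmax takes the earliest tie
        if corrected and new - corrected[-1] < refractory:
            continue  # collision/near-duplicate: keep the earlier original
        corrected.append(new)
    return RPeakSet(np.asarray(corrected, dtype=int), peaks.fs, peaks.source)


def match_peaks(
    detected: RPeakSet, truth: RPeakSet, tolerance_s: float = 0.050
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to ground truth.

    Returns ``(true_positives, false_positives, false_negatives)`` at the
    given time tolerance — the bookkeeping behind detector sensitivity
    (TP / (TP+FN)) and positive predictive value (TP / (TP+FP)).
    """
    tol = tolerance_s * truth.fs
    det = detected.indices * (truth.fs / detected.fs)
    used = np.zeros(len(truth.indices), dtype=bool)
    tp = 0
    for d in det:
        diffs = np.abs(truth.indices - d)
        diffs[used] = np.inf
        if len(diffs) and diffs.min() <= tol:
            used[int(np.argmin(diffs))] = True
            tp += 1
    fp = len(det) - tp
    fn = len(truth.indices) - tp
    return tp, fp, fn
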