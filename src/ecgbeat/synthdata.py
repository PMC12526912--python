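"""Synthetic single-lead ECG with known ground truth.

Every downstream stage (denoising, baseline removal, QRS detection, feature
extraction, classification, streaming) is tested against records produced
here, so the generator keeps full provenance: the clean beat train, the
additive high-frequency noise and the baseline wander are stored separately
and always sum back to the emitted signal.

Beats are modelled as sums of Gaussians (P wave, Q dip, R spike, S dip,
T wave) — not a physiological simulator, but enough structure for a QRS
detector and for class-separable morphology:

* N — ordinary P-QRS-T complex;
* S — reduced P wave and a shortened *preceding* RR interval (premature);
* V — wide, tall QRS, absent P, inverted T;
* F — interpolation between the N and V shapes;
* Q — low-amplitude, narrow, degenerate complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AAMI_CLASSES = ("N", "S", "V", "F", "Q")

#: relative span of a rendered beat around the R sample, seconds
_BEAT_SPAN = (-0.35, 0.45)
#: fraction by which the RR interval preceding an S (premature) beat shrinks
_S_PREMATURITY = 0.65


class SynthError(ValueError):
    """Invalid synthetic-record configuration."""


@dataclass(frozen=True)
class SyntheticBeatSpec:
    """Template parameters for one AAMI beat class.

    Amplitudes are in mV, widths in seconds.  ``t_sign`` lets ventricular
    shapes invert the T wave without flipping the whole complex
    (``polarity`` does that).
    """

    aami_class: str
    qrs_amplitude: float = 1.0
    qrs_width: float = 0.08
    p_amplitude: float = 0.15
    t_amplitude: float = 0.30
    polarity: int = 1
    t_sign: int = 1

    def __post_init__(self) -> None:
        if self.aami_class not in AAMI_CLASSES:
            raise SynthError(f"unknown AAMI class {self.aami_class!r}")
        if not 0 < self.qrs_width < 0.2:
            raise SynthError("qrs_width must lie in (0, 0.2) s")
        if self.qrs_amplitude <= 0:
            raise SynthError("qrs_amplitude must be positive")
        if self.p_amplitude < 0 or self.t_amplitude < 0:
            raise SynthError("P/T amplitudes must be non-negative")
        if self.polarity not in (-1, 1) or self.t_sign not in (-1, 1):
            raise SynthError("polarity and t_sign must be +1 or -1")

    def render(self, fs: float) -> np.ndarray:
        """Sample the beat template on ``fs`` over the canonical beat span.

        The R spike is centred on the sample at relative time 0; it is the
        template's global extremum, so ground-truth R-peak indices coincide
        with the local argmax used by the correction step.
        """
        n_left = int(round(-_BEAT_SPAN[0] * fs))
        n_right = int(round(_BEAT_SPAN[1] * fs))
        tau = np.arange(-n_left, n_right + 1) / fs
        sig_r = self.qrs_width / 5.0

        def gauss(center: float, sigma: float) -> np.ndarray:
            return np.exp(-0.5 * ((tau - center) / sigma) ** 2)

        wave = (
            self.p_amplitude * gauss(-0.20, 0.025)
            - 0.15 * self.qrs_amplitude * gauss(-0.6 * self.qrs_width, sig_r / 2)
            + self.qrs_amplitude * gauss(0.0, sig_r)
            - 0.20 * self.qrs_amplitude * gauss(0.6 * self.qrs_width, sig_r / 2)
            + self.t_sign * self.t_amplitude * gauss(0.30, 0.06)
        )
        return self.polarity * wave

    @property
    def r_offset(self) -> float:
        """Seconds from template start to the R sample."""
        return -_BEAT_SPAN[0]


def default_templates() -> list[SyntheticBeatSpec]:
    """One template per AAMI class, mutually distinct hence learnable."""
    return [
        SyntheticBeatSpec("N"),
        SyntheticBeatSpec("S", qrs_amplitude=0.9, qrs_width=0.07,
                          p_amplitude=0.05, t_amplitude=0.25),
        SyntheticBeatSpec("V", qrs_amplitude=1.5, qrs_width=0.16,
                          p_amplitude=0.0, t_amplitude=0.40, t_sign=-1),
        SyntheticBeatSpec("F", qrs_amplitude=1.25, qrs_width=0.12,
                          p_amplitude=0.07, t_amplitude=0.12, t_sign=-1),
        SyntheticBeatSpec("Q", qrs_amplitude=0.5, qrs_width=0.05,
                          p_amplitude=0.0, t_amplitude=0.08),
    ]


@dataclass(frozen=True)
class SyntheticRecordConfig:
    """Generation parameters for one synthetic record.

    ``rr_mean`` defaults inside the 0.6–1.0 s band of normal adult
    inter-beat intervals; ``t_start`` places the first beat late enough
    that its full morphology window exists.
    """

    duration: float = 60.0
    fs: float = 360.0
    rr_mean: float = 0.8
    rr_jitter_sd: float = 0.0
    class_mix: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0)
    hf_noise_sd: float = 0.0
    baseline_amplitude: float = 0.0
    baseline_freq: float = 0.25
    seed: int = 0
    t_start: float = 1.0

    def __post_init__(self) -> None:
        if self.fs not in (130.0, 360.0, 130, 360):
            raise SynthError("fs must be 130 or 360 Hz")
        if not 0.6 <= self.rr_mean <= 1.0:
            raise SynthError("rr_mean must lie in [0.6, 1.0] s")
        if self.rr_jitter_sd < 0:
            raise SynthError("rr_jitter_sd must be non-negative")
        if len(self.class_mix) != len(AAMI_CLASSES):
            raise SynthError("class_mix must have 5 entries")
        if abs(sum(self.class_mix) - 1.0) > 1e-9 or min(self.class_mix) < 0:
            raise SynthError("class_mix must be a probability vector summing to 1")
        if self.hf_noise_sd < 0 or self.baseline_amplitude < 0:
            raise SynthError("noise/baseline amplitudes must be non-negative")
        if not 0 <= self.baseline_freq < 0.5:
            raise SynthError("baseline_freq must lie in [0, 0.5) Hz")
        if self.duration <= self.t_start + 1.0:
            raise SynthError("duration too short for the configured t_start")


@dataclass
class SyntheticRecord:
    """A generated record plus its ground truth and additive components."""

    signal: np.ndarray
    fs: float
    true_rpeaks: np.ndarray          # sample indices, strictly increasing
    true_labels: list[str]           # AAMI class per beat
    clean: np.ndarray = field(repr=False, default=None)
    noise: np.ndarray = field(repr=False, default=None)
    baseline: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if len(self.true_rpeaks) != len(self.true_labels):
            raise SynthError("rpeaks/labels length mismatch")
        if len(self.true_rpeaks) and (
            self.true_rpeaks.min() < 0 or self.true_rpeaks.max() >= len(self.signal)
        ):
            raise SynthError("R-peak index out of signal bounds")
        if np.any(np.diff(self.true_rpeaks) <= 0):
            raise SynthError("R-peak indices must be strictly increasing")


def generate_record(
    config: SyntheticRecordConfig,
    templates: list[SyntheticBeatSpec] | None = None,
) -> SyntheticRecord:
    """Generate a synthetic ECG record.

    Beat times accumulate truncated-normal RR draws starting from
    ``t_start``; each beat's class follows ``class_mix``; an S beat
    shortens the interval that precedes it (prematurity).  The emitted
    signal is exactly ``clean + noise + baseline``.
    """
    templates = default_templates() if templates is None else templates
    by_class = {t.aami_class: t for t in templates}
    missing = [c for c, p in zip(AAMI_CLASSES, config.class_mix)
               if p > 0 and c not in by_class]
    if missing:
        raise SynthError(f"class_mix requires templates for {missing}")
    max_width = max(t.qrs_width for t in by_class.values())
    if config.rr_mean - 3.0 * config.rr_jitter_sd <= max_width:
        raise SynthError("rr_mean - 3*rr_jitter_sd must exceed the QRS width")

    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration * config.fs))
    clean = np.zeros(n)
    tail = -_BEAT_SPAN[1]  # leave room for the T wave of the last beat

    def draw_class() -> str:
        return AAMI_CLASSES[rng.choice(len(AAMI_CLASSES), p=config.class_mix)]

    def draw_rr() -> float:
        if config.rr_jitter_sd == 0:
            return config.rr_mean
        while True:  # truncate to positive, clear of the refractory zone
            rr = config.rr_mean + config.rr_jitter_sd * rng.standard_normal()
            if rr > max(0.25, 2 * max_width):
                return rr

    beat_times = [config.t_start]
    labels = [draw_class()]
    while True:
        cls = draw_class()
        rr = draw_rr()
        if cls == "S":  # premature: the interval *preceding* an S beat shrinks
            rr *= _S_PREMATURITY
        t_next = beat_times[-1] + rr
        if t_next >= config.duration + tail:
            break
        beat_times.append(t_next)
        labels.append(cls)

    rpeaks = []
    kept_labels = []
    for bt, cls in zip(beat_times, labels):
        r_idx = int(round(bt * config.fs))
        if r_idx >= n:
            continue
        tpl = by_class[cls].render(config.fs)
        start = r_idx - int(round(by_class[cls].r_offset * config.fs))
        sl_lo = max(start, 0)
        sl_hi = min(start + len(tpl), n)
        clean[sl_lo:sl_hi] += tpl[sl_lo - start:sl_hi - start]
        rpeaks.append(r_idx)
        kept_labels.append(cls)

    noise = (config.hf_noise_sd * rng.standard_normal(n)
             if config.hf_noise_sd > 0 else np.zeros(n))
    tgrid = np.arange(n) / config.fs
    baseline = (config.baseline_amplitude
                * np.sin(2 * np.pi * config.baseline_freq * tgrid)
                if config.baseline_amplitude > 0 else np.zeros(n))

    return SyntheticRecord(
        signal=clean + noise + baseline,
        fs=config.fs,
        true_rpeaks=np.asarray(rpeaks, dtype=int),
        true_labels=kept_labels,
        clean=clean,
        noise=noise,
        baseline=baseline,
    )


def decompose_record(record: SyntheticRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return ``(clean, noise, baseline)``; their sum is the stored signal."""
    if record.clean is None or record.noise is None or record.baseline is None:
        raise SynthError("record does not carry its components")
    return record.clean, record.noise, record.baseline


# ---------------------------------------------------------------------------
# Separable class datasets for classifier tests
# ---------------------------------------------------------------------------

# Class-conditional RR-dynamics centroids, one row per AAMI class, in the
# 9-feature order (RR0, RR-1, RR+1, RR0/avg, RR-1/avg, RR+1/avg,
# RR-1/RR0, RR+1/RR0, tRR0).  N is the regular-rhythm reference; S/V are
# premature with compensatory pauses of different depth; F is mildly
# premature; Q follows a pause.
_RRI_CENTROIDS = np.array([
    [0.80, 0.80, 0.80, 1.00, 1.00, 1.00, 1.00, 1.00, 0.0],
    [0.55, 0.80, 0.95, 0.69, 1.00, 1.19, 1.45, 1.73, -2.5],
    [0.62, 0.80, 1.05, 0.78, 1.00, 1.31, 1.29, 1.69, -1.8],
    [0.70, 0.80, 0.85, 0.88, 1.00, 1.06, 1.14, 1.21, -1.0],
    [0.90, 0.70, 0.75, 1.20, 0.93, 1.00, 0.78, 0.83, 1.5],
])

#: realistic per-dimension noise for the two dataset kinds (RR jitter of a
#: few tens of ms; segment noise relative to a ~1 mV QRS)
_DATASET_NOISE_SD = {"rri": 0.12, "segment": 0.15}


def make_separable_dataset(
    n_samples: int,
    kind: str = "segment",
    length: int = 100,
    noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a 5-class dataset whose classes are separable by construction.

    ``kind='segment'`` yields z-scored morphology templates resampled to
    ``length`` samples plus Gaussian noise; ``kind='rri'`` yields the
    9-dimensional RR-dynamics centroids plus noise (``length`` is then
    fixed at 9).  Returns ``(X, y)`` with integer labels indexing
    :data:`AAMI_CLASSES`.
    """
    if kind not in _DATASET_NOISE_SD:
        raise SynthError(f"unknown dataset kind {kind!r}")
    sd = _DATASET_NOISE_SD[kind] if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    y = rng.integers(0, len(AAMI_CLASSES), size=n_samples)

    if kind == "rri":
        centroids = _RRI_CENTROIDS
    else:
        fs = 360.0
        centroids = []
        for tpl in default_templates():
            wave = tpl.render(fs)
            r = int(round(tpl.r_offset * fs))
            half = 90
            seg = wave[r - half:r + half + 1]
            seg = (seg - seg.mean()) / seg.std()
            xs = np.linspace(0, len(seg) - 1, length)
            centroids.append(np.interp(xs, np.arange(len(seg)), seg))
        centroids = np.asarray(centroids)

    X = centroids[y] + sd * rng.standard_normal((n_samples, centroids.shape[1]))
    return X, y


def nearest_template_labels(segments: np.ndarray) -> list[str]:
    """Classify z-scored segments by nearest (z-scored) class template.

    A deliberately trivial classifier used to guard template distinctness:
    on noiseless synthetic segments it must be perfect.
    """
    length = segments.shape[1]
    fs = 360.0
    centroids = []
    for tpl in default_templates():
        wave = tpl.render(fs)
        r = int(round(tpl.r_offset * fs))
        seg = wave[r - 90:r + 91]
        seg = (seg - seg.mean()) / seg.std()
        xs = np.linspace(0, len(seg) - 1, length)
        centroids.append(np.interp(xs, np.arange(len(seg)), seg))
    centroids = np.asarray(centroids)
    out = []
    for row in segments:
        z = (row - row.mean()) / row.std()
        d = np.linalg.norm(centroids - z, axis=1)
        out.append(AAMI_CLASSES[int(np.argmin(d))])
    return out
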