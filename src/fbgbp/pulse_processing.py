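"""Pulse-wave conditioning: band-pass, beat segmentation, averaging.

The wavelength-shift trace measured at a pulsation point approximates the
acceleration pulse wave.  Processing follows the standard ensemble-average
recipe: band-pass 0.5-5 Hz, detect the dominant systolic peak of every beat
(peak A), cut a window around each anchor, resample windows to a common
length with anchors aligned, average pointwise, and rescale the averaged
beat so its minimum is 0 and the anchor is 1.  The normalized beat is the
explanatory-variable vector used by the calibration model.

Acceleration-pulse-wave morphology carries five characteristic extrema,
labeled A-E: A the early systolic positive wave, B the early systolic
negative wave, C the late systolic re-increasing wave, D the late systolic
re-decreasing wave, and E the early diastolic positive wave.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import (
    DegenerateBeatError,
    DegenerateSignalError,
    InsufficientBeatsError,
    DomainError,
    RecordTooShortError,
)

__all__ = [
    "PulseSignal",
    "Beat",
    "NormalizedBeat",
    "PeakSet",
    "bandpass",
    "segment_beats",
    "average_and_normalize",
    "second_derivative",
    "detect_peaks_ABCDE",
]

MIN_BANDPASS_SECONDS = 3.0
DEFAULT_BEAT_LENGTH = 100
DEFAULT_ANCHOR_FRACTION = 0.3


@dataclass
class PulseSignal:
    """Band-passed pulse-wave samples (zero-mean by construction)."""

    x: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or not np.all(np.isfinite(self.x)):
            raise DomainError("x must be a finite 1-D array")
        if self.fs <= 0:
            raise DomainError("fs must be positive")

    @property
    def duration(self) -> float:
        return self.x.size / self.fs


@dataclass
class Beat:
    """One-pulse waveform window anchored at its systolic peak (peak A).

    ``start_index`` is the window's offset in the source signal when the
    beat came from segmentation (None for synthetic beats).
    """

    samples: np.ndarray
    anchor_index: int
    start_index: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size < 8:
            raise DomainError("a beat must contain at least 8 samples")
        if not 0 <= self.anchor_index < self.samples.size:
            raise DomainError("anchor_index out of range")


@dataclass
class NormalizedBeat:
    """Length-standardized beat with min 0 and anchor (systolic peak) 1."""

    samples: np.ndarray
    anchor_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        s = self.samples
        if not 0 <= self.anchor_index < s.size:
            raise DomainError("anchor_index out of range")
        if s.min() != 0.0 or s[self.anchor_index] != 1.0 or s.max() > 1.0:
            raise DomainError(
                "normalized beat must have min 0, anchor 1 and values in [0, 1]"
            )

    @property
    def L(self) -> int:
        return self.samples.size


@dataclass
class PeakSet:
    """Positions (beat-length fractions) and amplitudes of peaks A-E.

    Amplitudes are measured relative to the beat mean, so the positive waves
    (A, C, E) come out positive and the negative waves (B, D) negative for
    typical morphologies.  An extremum that does not exist in the beat is
    reported as None, never fabricated.
    """

    positions: dict
    amplitudes: dict

    def present(self) -> list[str]:
        return [k for k in "ABCDE" if self.positions.get(k) is not None]


def bandpass(
    raw, fs: float, f_lo: float = 0.5, f_hi: float = 5.0
) -> PulseSignal:
    """Zero-phase 0.5-5 Hz band-pass of a raw trace.

    Cascaded 4th-order Butterworth high-pass and low-pass corners applied
    forward-backward (``sosfiltfilt``), so the passband is flat to within a
    few percent at the geometric-mean frequency and DC and mains frequencies
    are strongly rejected without phase distortion.
    """
    raw = np.asarray(raw, dtype=float)
    if not 0 < f_lo < f_hi:
        raise DomainError("need 0 < f_lo < f_hi")
    if fs <= 2.0 * f_hi:
        raise DomainError("fs must exceed twice the upper band edge")
    if raw.size / fs <= MIN_BANDPASS_SECONDS:
        raise RecordTooShortError(
            f"band-pass needs more than {MIN_BANDPASS_SECONDS:.0f} s of signal "
            f"(got {raw.size / fs:.2f} s)"
        )
    sos = np.vstack(
        [
            sps.butter(4, f_lo, btype="highpass", fs=fs, output="sos"),
            sps.butter(4, f_hi, btype="lowpass", fs=fs, output="sos"),
        ]
    )
    return PulseSignal(x=sps.sosfiltfilt(sos, raw), fs=fs)


def _beat_period_samples(
    x: np.ndarray, fs: float, min_bpm: float, max_bpm: float
) -> int:
    """Dominant beat period (samples) from the autocorrelation peak.

    The lag search is restricted to periods between 60/max_bpm and
    60/min_bpm seconds.
    """
    lag_lo = max(1, int(round(60.0 / max_bpm * fs)))
    lag_hi = min(x.size - 1, int(round(60.0 / min_bpm * fs)))
    if lag_hi <= lag_lo:
        raise InsufficientBeatsError("record too short to estimate a beat period")
    n_fft = int(2 ** np.ceil(np.log2(2 * x.size)))
    spectrum = np.fft.rfft(x - x.mean(), n_fft)
    acf = np.fft.irfft(spectrum * np.conj(spectrum), n_fft)[: lag_hi + 1]
    return int(lag_lo + np.argmax(acf[lag_lo : lag_hi + 1]))


def segment_beats(
    sig: PulseSignal, min_bpm: float = 40.0, max_bpm: float = 180.0
) -> list[Beat]:
    """Cut the signal into per-beat windows anchored at systolic peaks.

    Anchors are the dominant positive peaks: the beat period is estimated
    from the signal's autocorrelation within the [min_bpm, max_bpm] lag
    range, and peaks must be separated by at least 75% of that period (never
    less than ``60/max_bpm`` seconds) with prominence at least 30% of the
    signal's robust amplitude (90th percentile of |x|).  Each window runs
    from 30% of the median inter-peak interval before its anchor to 70%
    after; windows truncated by the record boundary are discarded.
    """
    if sig.duration < 5.0:
        raise RecordTooShortError("segmentation needs at least 5 s of signal")
    x = sig.x
    robust_amp = np.percentile(np.abs(x), 90)
    if robust_amp <= 0:
        raise InsufficientBeatsError("flat signal: no beats detectable")
    period = _beat_period_samples(x, sig.fs, min_bpm, max_bpm)
    distance = max(int(round(0.75 * period)), int(round(60.0 / max_bpm * sig.fs)), 1)
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=0.3 * robust_amp)
    if peaks.size < 3:
        raise InsufficientBeatsError(
            f"only {peaks.size} beats detected; need at least 3"
        )
    median_ipi = float(np.median(np.diff(peaks)))
    pre = int(round(0.3 * median_ipi))
    post = int(round(0.7 * median_ipi))
    beats = []
    for p in peaks:
        start, stop = p - pre, p + post
        if start < 0 or stop > x.size:
            continue
        beats.append(
            Beat(samples=x[start:stop], anchor_index=pre, start_index=int(start))
        )
    if len(beats) < 3:
        raise InsufficientBeatsError("fewer than 3 complete beats in record")
    return beats


def _resample_anchored(beat: Beat, L: int, anchor: int) -> np.ndarray:
    """Linear resample to length L with the anchor pinned at index `anchor`."""
    s, a = beat.samples, beat.anchor_index
    n = s.size
    out = np.empty(L)
    if a == 0:
        pre = np.full(anchor + 1, s[0])
    else:
        pre = np.interp(np.linspace(0.0, a, anchor + 1), np.arange(n), s)
    if a == n - 1:
        post = np.full(L - anchor, s[-1])
    else:
        post = np.interp(
            np.linspace(a, n - 1.0, L - anchor), np.arange(n), s
        )
    out[: anchor + 1] = pre
    out[anchor:] = post
    return out


def average_and_normalize(
    beats: list[Beat],
    L: int = DEFAULT_BEAT_LENGTH,
    anchor_fraction: float = DEFAULT_ANCHOR_FRACTION,
    normalize_each: bool = False,
) -> NormalizedBeat:
    """Ensemble-average beats and rescale to the [0, 1] convention.

    Each beat is linearly resampled to ``L`` samples with its anchor pinned
    at ``round(anchor_fraction * L)``, the pointwise mean is taken, and the
    average is affinely rescaled so the minimum is exactly 0 and the anchor
    ("clipping position", the systolic peak) exactly 1.

    ``normalize_each=True`` rescales every beat to [0, 1] before averaging
    instead (the two orders differ only when beat amplitudes vary).
    """
    if len(beats) < 3:
        raise InsufficientBeatsError("averaging needs at least 3 beats")
    if L < 8:
        raise DomainError("L must be at least 8")
    anchor = int(round(anchor_fraction * L))
    if not 0 <= anchor < L:
        raise DomainError("anchor_fraction places the anchor out of range")
    rows = np.array([_resample_anchored(b, L, anchor) for b in beats])
    if normalize_each:
        lo = rows.min(axis=1, keepdims=True)
        peak = rows[:, anchor][:, None]
        span = peak - lo
        if np.any(span <= 0):
            raise DegenerateBeatError("a beat's anchor equals its minimum")
        rows = (rows - lo) / span
    mean = rows.mean(axis=0)
    # the systolic peak of the averaged beat is its global max; under noise
    # it may sit a sample or two off the alignment anchor, but never far
    peak = int(np.argmax(mean))
    if abs(peak - anchor) > max(2, int(0.05 * L)):
        raise DegenerateBeatError(
            "averaged beat's maximum is far from the alignment anchor; "
            "beats are misaligned"
        )
    lo = mean.min()
    span = mean[peak] - lo
    if span <= 0:
        raise DegenerateBeatError(
            "averaged beat's anchor value equals its minimum; cannot normalize"
        )
    out = (mean - lo) / span
    return NormalizedBeat(samples=out, anchor_index=peak)


def second_derivative(samples, fs_effective: float) -> np.ndarray:
    """Second time derivative by central differences.

    Interior samples use ``(x[i+1] - 2 x[i] + x[i-1]) / dt**2``; the
    endpoints copy the one-sided second difference of their neighbor.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 5:
        raise DomainError("second derivative needs at least 5 samples")
    if fs_effective <= 0:
        raise DomainError("fs_effective must be positive")
    dt2 = (1.0 / fs_effective) ** 2
    d2 = np.empty_like(x)
    d2[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt2
    d2[0] = (x[2] - 2.0 * x[1] + x[0]) / dt2
    d2[-1] = (x[-1] - 2.0 * x[-2] + x[-3]) / dt2
    return d2


def detect_peaks_ABCDE(beat: NormalizedBeat) -> PeakSet:
    """Locate the A-E extrema of a normalized beat.

    A is the global maximum (the systolic anchor); B is the first local
    minimum after A, C the first local maximum after B, D the next local
    minimum and E the next local maximum.  Amplitudes are reported relative
    to the beat mean; positions as fractions of the beat length.  Absent
    extrema are None.
    """
    x = beat.samples
    if np.ptp(x) == 0:
        raise DegenerateSignalError("flat beat: no global maximum distinguishable")
    L = x.size
    centered = x - x.mean()
    positions: dict = {k: None for k in "ABCDE"}
    amplitudes: dict = {k: None for k in "ABCDE"}

    a_idx = int(np.argmax(x))
    positions["A"] = a_idx / L
    amplitudes["A"] = float(centered[a_idx])

    minima, _ = sps.find_peaks(-x)
    maxima, _ = sps.find_peaks(x)
    cursor = a_idx
    for label, pool in zip("BCDE", (minima, maxima, minima, maxima)):
        nxt = pool[pool > cursor]
        if nxt.size == 0:
            break
        idx = int(nxt[0])
        positions[label] = idx / L
        amplitudes[label] = float(centered[idx])
        cursor = idx
    return PeakSet(positions=positions, amplitudes=amplitudes)
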