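"""Synthetic subjects: pulse morphology covarying with a latent blood pressure.

The generator stands in for the sensor-on-wrist measurement.  Each subject
has a five-bump beat template (Gaussian bumps at the A-E positions of an
acceleration pulse wave, A positive and dominant, B and D negative, C and E
positive) whose bump amplitudes drift linearly with the latent blood
pressure.  A record tiles jittered copies of the template at the subject's
heart rate, scales to interferometric phase, adds a sub-0.2 Hz baseline
drift (removed downstream by the band-pass), and encodes the phase through
the three-phase interferometer model with additive detector noise.  The cuff
reference reading is the latent pressure plus Gaussian measurement error.

The linear morphology-pressure coupling is the minimal structure under which
a linear (PLS) calibration curve is the correct model; it emulates the
premise that the pulse waveform carries blood-pressure information.

All randomness flows from one master seed through named, disjoint
sub-streams (per subject / record / noise source).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .interferometry import PhaseTrace, ThreePhaseRecord, simulate_three_phase

__all__ = [
    "SubjectParams",
    "SubjectDataset",
    "make_beat_template",
    "simulate_record",
    "simulate_subject",
    "default_subjects",
]

DEFAULT_FS = 10_000.0
DEFAULT_DURATION_S = 20.0
#: A-E bump centers/widths as fractions of the beat period, and base
#: amplitudes at the subject's mean pressure (A dominant positive; B, D
#: negative; C, E positive), wide enough that the beat's spectral energy
#: sits almost entirely inside the 0.5-5 Hz analysis band.
BASE_CENTERS = (0.14, 0.28, 0.45, 0.60, 0.76)
BASE_WIDTHS = (0.055, 0.060, 0.075, 0.075, 0.085)
BASE_AMPS = (1.0, -0.45, 0.35, -0.25, 0.20)
#: Per-component amplitude slope per mmHg: higher pressure raises the late
#: systolic re-increasing wave (C) and deepens B/D, the dominant directions
#: in which acceleration-pulse-wave morphology tracks pressure.
BASE_SENSITIVITY = (0.0, -0.004, 0.008, -0.005, 0.004)


@dataclass
class SubjectParams:
    """Data-generating parameters of one synthetic subject."""

    bp_mean: float = 111.3
    bp_sd: float = 5.5
    heart_rate_bpm: float = 68.0
    bump_centers: np.ndarray = field(default_factory=lambda: np.array(BASE_CENTERS))
    bump_widths: np.ndarray = field(default_factory=lambda: np.array(BASE_WIDTHS))
    bump_amps: np.ndarray = field(default_factory=lambda: np.array(BASE_AMPS))
    bp_sensitivity: np.ndarray = field(
        default_factory=lambda: np.array(BASE_SENSITIVITY)
    )
    ref_noise_sd: float = 2.0     # cuff-reference error, mmHg
    detector_noise_sd: float = 0.01  # additive detector noise, voltage units
    phase_gain: float = 2.5       # rad of interferometric phase per unit waveform
    drift_amp: float = 0.8        # rad, baseline wander amplitude
    drift_freq: float = 0.08      # Hz, well below the 0.5 Hz band edge
    subject_id: str = "A"

    def __post_init__(self) -> None:
        self.bump_centers = np.asarray(self.bump_centers, dtype=float)
        self.bump_widths = np.asarray(self.bump_widths, dtype=float)
        self.bump_amps = np.asarray(self.bump_amps, dtype=float)
        self.bp_sensitivity = np.asarray(self.bp_sensitivity, dtype=float)
        if self.bp_sd < 0 or self.ref_noise_sd < 0 or self.detector_noise_sd < 0:
            raise DomainError("noise standard deviations must be >= 0")
        if not 40.0 <= self.heart_rate_bpm <= 180.0:
            raise DomainError("heart_rate_bpm must lie in [40, 180]")
        c = self.bump_centers
        if c.shape != (5,) or np.any(np.diff(c) <= 0) or c[0] <= 0 or c[-1] >= 1:
            raise DomainError("bump centers must be strictly increasing in (0, 1)")
        if np.any(self.bump_widths <= 0):
            raise DomainError("bump widths must be positive")
        a = self.bump_amps
        if a[0] <= 0 or a[0] < np.abs(a[1:]).max():
            raise DomainError("bump A must be positive and dominant")


@dataclass
class SubjectDataset:
    """Calibration and validation record sets for one synthetic subject."""

    subject_id: str
    seed: int
    calibration_records: list
    calibration_bp: np.ndarray      # reference (cuff) readings, mmHg
    validation_records: list
    validation_bp: np.ndarray
    calibration_latent: np.ndarray  # true latent pressures, mmHg
    validation_latent: np.ndarray


def make_beat_template(params: SubjectParams, bp: float, n_samples: int) -> np.ndarray:
    """Render one beat period at a given latent blood pressure.

    Sum of five Gaussian bumps over beat fraction u in [0, 1) with
    amplitudes ``base + slope * (bp - bp_mean)``.  Deterministic in
    (params, bp).
    """
    if n_samples < 2:
        raise DomainError("n_samples must be >= 2")
    amps = params.bump_amps + params.bp_sensitivity * (bp - params.bp_mean)
    u = np.arange(n_samples) / n_samples
    out = np.zeros(n_samples)
    for a, c, w in zip(amps, params.bump_centers, params.bump_widths):
        out += a * np.exp(-0.5 * ((u - c) / w) ** 2)
    return out


def simulate_record(
    params: SubjectParams,
    bp: float,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
    seed: int | np.random.Generator | None = None,
) -> ThreePhaseRecord:
    """One 20 s three-phase sensor record at a fixed latent pressure.

    Beat templates are tiled at the subject heart rate with +/-3% uniform
    beat-interval jitter, scaled by ``phase_gain`` to an interferometric
    phase trace, given a slow sinusoidal baseline drift, and encoded through
    the three-phase detector model with additive Gaussian detector noise.
    """
    if duration_s < 5.0:
        raise DomainError("records must be at least 5 s long")
    rng = np.random.default_rng(seed)
    n_total = int(round(duration_s * fs))
    period = 60.0 / params.heart_rate_bpm
    pieces, filled = [], 0
    while filled < n_total:
        jitter = 1.0 + rng.uniform(-0.03, 0.03)
        n_beat = max(2, int(round(period * jitter * fs)))
        pieces.append(make_beat_template(params, bp, n_beat))
        filled += n_beat
    waveform = np.concatenate(pieces)[:n_total]
    t = np.arange(n_total) / fs
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    phi = params.phase_gain * waveform + params.drift_amp * np.sin(
        2.0 * np.pi * params.drift_freq * t + drift_phase
    )
    return simulate_three_phase(
        PhaseTrace(phi=phi, fs=fs),
        gains=(1.0, 1.0, 1.0),
        offset=1.0,
        noise_sd=params.detector_noise_sd,
        seed=rng,
    )


def simulate_subject(
    params: SubjectParams,
    n_cal: int = 50,
    n_val: int = 25,
    seed: int = 0,
    duration_s: float = DEFAULT_DURATION_S,
    fs: float = DEFAULT_FS,
) -> SubjectDataset:
    """Generate calibration (default 50) and validation (default 25) records.

    Each record's latent pressure is drawn from Normal(bp_mean, bp_sd); the
    cuff reference is the latent plus Normal(0, ref_noise_sd) reading error.
    Calibration and validation use disjoint sub-seeds of ``seed``.
    """
    if n_cal < 1 or n_val < 0:
        raise DomainError("need n_cal >= 1 and n_val >= 0")
    root = np.random.SeedSequence(seed)
    cal_ss, val_ss = root.spawn(2)

    def _split(ss, n):
        latent_rng = np.random.default_rng(ss.spawn(1)[0])
        latent = params.bp_mean + params.bp_sd * latent_rng.standard_normal(n)
        refs = latent + (
            params.ref_noise_sd * latent_rng.standard_normal(n)
            if params.ref_noise_sd > 0
            else 0.0
        )
        record_streams = ss.spawn(n)
        records = [
            simulate_record(
                params, latent[i], duration_s=duration_s, fs=fs,
                seed=np.random.default_rng(record_streams[i]),
            )
            for i in range(n)
        ]
        return records, np.asarray(refs, dtype=float), latent

    cal_records, cal_refs, cal_latent = _split(cal_ss, n_cal)
    val_records, val_refs, val_latent = _split(val_ss, n_val)
    return SubjectDataset(
        subject_id=params.subject_id,
        seed=seed,
        calibration_records=cal_records,
        calibration_bp=cal_refs,
        validation_records=val_records,
        validation_bp=val_refs,
        calibration_latent=cal_latent,
        validation_latent=val_latent,
    )


def default_subjects() -> list[SubjectParams]:
    """Three healthy-subject presets with distinct pressures and morphologies.

    Mean pressures and within-subject spreads follow the three-subject study
    design (means 111.3, 123.1 and 100.9 mmHg; per-subject ranges of roughly
    18-25 mmHg over 50 records, i.e. standard deviations near 4-5.5 mmHg, so
    the pooled set spans about +/-20 mmHg); morphologies and pressure
    sensitivities differ between subjects so that a pooled calibration curve
    is a genuine compromise across individuals.
    """
    a = SubjectParams(subject_id="A", bp_mean=111.3, bp_sd=5.5, heart_rate_bpm=68.0)
    b = SubjectParams(
        subject_id="B",
        bp_mean=123.1,
        bp_sd=5.0,
        heart_rate_bpm=74.0,
        bump_centers=np.array((0.13, 0.26, 0.43, 0.58, 0.74)),
        bump_amps=np.array((1.0, -0.55, 0.28, -0.30, 0.16)),
        bp_sensitivity=np.array((0.0, -0.006, 0.007, -0.004, 0.003)),
    )
    c = SubjectParams(
        subject_id="C",
        bp_mean=100.9,
        bp_sd=4.0,
        heart_rate_bpm=61.0,
        bump_centers=np.array((0.15, 0.30, 0.47, 0.62, 0.78)),
        bump_amps=np.array((1.0, -0.38, 0.42, -0.20, 0.24)),
        bp_sensitivity=np.array((0.0, -0.003, 0.009, -0.006, 0.005)),
    )
    return [a, b, c]
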