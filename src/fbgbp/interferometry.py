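"""Three-phase Mach-Zehnder interrogation of a fiber Bragg grating.

An FBG reflects a narrow band centered on the Bragg wavelength
``lambda_B = 2 n_eff Lambda``.  Strain on the grating shifts ``lambda_B``;
the interrogator converts that shift into an interferometric phase

    phi = 2 pi n_eff d / lambda_B**2 * delta_lambda

where ``d`` is the optical path difference between the interferometer arms.
Three detectors observe the interference at phase offsets 0, 2pi/3 and
4pi/3, so the wrapped phase can be recovered per sample from

    tan(phi) = sqrt(3) (V2 - V3) / (V2 + V3 - 2 V1)

once channel amplitudes and offset are normalized to 1.  This module
simulates the detector outputs from a phase trace and demodulates them back
to phase and wavelength shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    DegenerateCalibrationError,
    DegenerateSignalError,
    DomainError,
)

__all__ = [
    "BraggConfig",
    "ThreePhaseRecord",
    "PhaseTrace",
    "WavelengthShiftTrace",
    "bragg_wavelength",
    "simulate_three_phase",
    "estimate_channel_calibration",
    "apply_calibration",
    "demodulate_phase",
    "phase_to_wavelength_shift",
]

#: Detector phase offsets (rad) of the three interference channels.
CHANNEL_OFFSETS = 2.0 * np.pi * np.arange(3) / 3.0


def bragg_wavelength(n_eff: float, grating_spacing: float) -> float:
    """Bragg wavelength ``2 * n_eff * Lambda`` (same length unit as input).

    Parameters
    ----------
    n_eff : float
        Effective refractive index of the fiber core.
    grating_spacing : float
        Grating pitch ``Lambda``.
    """
    if n_eff <= 0 or grating_spacing <= 0:
        raise DomainError("n_eff and grating_spacing must be strictly positive")
    return 2.0 * n_eff * grating_spacing


@dataclass(frozen=True)
class BraggConfig:
    """Optical constants of the sensor and interrogator.

    Either ``grating_spacing`` or ``bragg_wavelength`` may be omitted; the
    missing one is derived from ``lambda_B = 2 n_eff Lambda``.  When both are
    supplied they must agree to relative tolerance 1e-12.

    ``path_difference`` is the optical path difference ``d`` of the
    interferometer arms in meters (default 3.33 mm; whether the instrument
    constant is geometric or optical length is an instrument convention, so
    it is exposed as configuration).
    """

    n_eff: float = 1.5
    path_difference: float = 3.33e-3
    grating_spacing: float | None = None
    bragg_wavelength: float | None = None

    def __post_init__(self) -> None:
        if self.n_eff <= 0 or self.path_difference <= 0:
            raise DomainError("n_eff and path_difference must be positive")
        lam, spacing = self.bragg_wavelength, self.grating_spacing
        if lam is None and spacing is None:
            object.__setattr__(self, "bragg_wavelength", 1550e-9)
            object.__setattr__(
                self, "grating_spacing", 1550e-9 / (2.0 * self.n_eff)
            )
            return
        if spacing is not None and spacing <= 0:
            raise DomainError("grating_spacing must be positive")
        if lam is not None and lam <= 0:
            raise DomainError("bragg_wavelength must be positive")
        if lam is None:
            object.__setattr__(
                self, "bragg_wavelength", bragg_wavelength(self.n_eff, spacing)
            )
        elif spacing is None:
            object.__setattr__(
                self, "grating_spacing", lam / (2.0 * self.n_eff)
            )
        else:
            expected = bragg_wavelength(self.n_eff, spacing)
            if abs(lam - expected) > 1e-12 * expected:
                raise DomainError(
                    "bragg_wavelength inconsistent with 2*n_eff*grating_spacing: "
                    f"{lam!r} vs {expected!r}"
                )


def _as_trace(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise DomainError(f"{name} must be a 1-D array of length >= 1")
    if not np.all(np.isfinite(arr)):
        raise DomainError(f"{name} contains non-finite values")
    return arr


@dataclass
class ThreePhaseRecord:
    """Raw traces of the three interference detectors.

    ``gains`` and ``offset`` describe the channel model
    ``V_n = gain_n * (offset + cos(phi + 2 pi (n-1)/3))``; a normalized
    record has gains (1, 1, 1) and offset 1.
    """

    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    fs: float
    gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    offset: float = 1.0

    def __post_init__(self) -> None:
        self.v1 = _as_trace(self.v1, "v1")
        self.v2 = _as_trace(self.v2, "v2")
        self.v3 = _as_trace(self.v3, "v3")
        if not (self.v1.size == self.v2.size == self.v3.size):
            raise DomainError("the three channel traces must have equal length")
        if self.fs <= 0:
            raise DomainError("fs must be positive")
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (3,) or np.any(self.gains <= 0):
            raise DomainError("gains must be three positive numbers")

    def __len__(self) -> int:
        return self.v1.size

    @property
    def channels(self) -> np.ndarray:
        """Channels stacked as a (3, n) array."""
        return np.vstack([self.v1, self.v2, self.v3])


@dataclass
class PhaseTrace:
    """Unwrapped interferometric phase in radians per sample."""

    phi: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.phi = _as_trace(self.phi, "phi")
        if self.fs <= 0:
            raise DomainError("fs must be positive")


@dataclass
class WavelengthShiftTrace:
    """Bragg-wavelength shift in meters per sample."""

    dlambda: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.dlambda = _as_trace(self.dlambda, "dlambda")
        if self.fs <= 0:
            raise DomainError("fs must be positive")


def simulate_three_phase(
    phase: PhaseTrace,
    gains=(1.0, 1.0, 1.0),
    offset: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ThreePhaseRecord:
    """Render the three detector outputs for a phase trace.

    Channel ``n`` (1-based) is ``gain_n * (offset + cos(phi + 2pi(n-1)/3))``
    plus independent zero-mean Gaussian noise of standard deviation
    ``noise_sd``.  Reproducible given ``seed``.
    """
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    gains = np.asarray(gains, dtype=float)
    rng = np.random.default_rng(seed)
    phi = phase.phi
    chans = gains[:, None] * (offset + np.cos(phi[None, :] + CHANNEL_OFFSETS[:, None]))
    if noise_sd > 0:
        chans = chans + rng.normal(0.0, noise_sd, size=chans.shape)
    return ThreePhaseRecord(
        v1=chans[0], v2=chans[1], v3=chans[2],
        fs=phase.fs, gains=gains, offset=offset,
    )


def estimate_channel_calibration(
    record: ThreePhaseRecord,
) -> tuple[np.ndarray, float]:
    """Estimate channel gains and shared offset from a calibration sweep.

    The calibration measurement is taken with the sensor off the pulsation
    point while the phase sweeps through at least a full fringe, so each
    channel traverses its full envelope ``gain * (offset ± 1)``.  The gain is
    the half peak-to-peak range per channel; the offset is the envelope
    midpoint averaged over channels.
    """
    chans = record.channels
    hi, lo = chans.max(axis=1), chans.min(axis=1)
    span = hi - lo
    scale = np.max(np.abs(chans)) + 1e-300
    if np.any(span <= 1e-12 * scale):
        raise DegenerateCalibrationError(
            "a channel has zero peak-to-peak range; calibration sweep "
            "must cover a full 2*pi fringe"
        )
    gains = span / 2.0
    offset = float(np.mean((hi + lo) / (2.0 * gains)))
    return gains, offset


def apply_calibration(
    record: ThreePhaseRecord, gains, offset: float
) -> ThreePhaseRecord:
    """Normalize a record so channels follow ``1 + cos(...)`` (range [0, 2])."""
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (3,) or np.any(gains <= 0):
        raise DomainError("gains must be three positive numbers")
    chans = record.channels / gains[:, None] - (offset - 1.0)
    return replace(
        record, v1=chans[0], v2=chans[1], v3=chans[2],
        gains=np.ones(3), offset=1.0,
    )


def demodulate_phase(record: ThreePhaseRecord) -> PhaseTrace:
    """Recover the unwrapped phase from a normalized three-phase record.

    For normalized channels the quadrature pair is
    ``sqrt(3)(V2 - V3) = -3 sin(phi)`` and ``V2 + V3 - 2 V1 = -3 cos(phi)``,
    so ``arctan2(-num, -den)`` returns phi wrapped to (-pi, pi], which is
    then unwrapped by continuity.  Recovers the generating phase up to a
    global multiple of 2*pi.

    Samples where numerator and denominator both vanish (all channels equal)
    carry no phase information; they are filled by linear interpolation from
    neighboring samples.  A record degenerate everywhere raises
    :class:`DegenerateSignalError`.
    """
    num = np.sqrt(3.0) * (record.v2 - record.v3)
    den = record.v2 + record.v3 - 2.0 * record.v1
    mag = np.hypot(num, den)
    tol = 1e-9 * (mag.max() + 1e-300)
    valid = mag > tol
    if not np.any(valid):
        raise DegenerateSignalError("all samples degenerate (channels equal)")
    wrapped = np.arctan2(-num[valid], -den[valid])
    unwrapped_valid = np.unwrap(wrapped)
    if valid.all():
        phi = unwrapped_valid
    else:
        idx = np.arange(len(record))
        phi = np.interp(idx, idx[valid], unwrapped_valid)
    return PhaseTrace(phi=phi, fs=record.fs)


def phase_to_wavelength_shift(
    phase: PhaseTrace, cfg: BraggConfig, remove_mean: bool = True
) -> WavelengthShiftTrace:
    """Convert phase to Bragg-wavelength shift.

    ``delta_lambda = phi * lambda_B**2 / (2 pi n_eff d)``.  Wavelength shifts
    are relative, so the trace mean is removed by default; pass
    ``remove_mean=False`` to apply the bare conversion factor.
    """
    phi = phase.phi - phase.phi.mean() if remove_mean else phase.phi
    factor = cfg.bragg_wavelength**2 / (2.0 * np.pi * cfg.n_eff * cfg.path_difference)
    return WavelengthShiftTrace(dlambda=phi * factor, fs=phase.fs)
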