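"""Named error classes raised across the pipeline."""


class FbgbpError(ValueError):
    """Base class for all package-specific errors."""


class DomainError(FbgbpError):
    """A physical parameter is outside its valid domain (e.g. non-positive)."""


class DegenerateCalibrationError(FbgbpError):
    """Calibration record has a channel with no peak-to-peak swing."""


class DegenerateSignalError(FbgbpError):
    """Signal carries no usable phase information (all channels equal)."""


class RecordTooShortError(FbgbpError):
    """Record shorter than the minimum required duration."""


class InsufficientBeatsError(FbgbpError):
    """Fewer beats detected than the processing step requires."""


class DegenerateBeatError(FbgbpError):
    """Beat normalization is undefined (anchor value equals the minimum)."""


class RankDeficiencyError(FbgbpError):
    """Requested more PLS factors than the centered data supports."""


class DimensionMismatchError(FbgbpError):
    """Input dimensions do not match the fitted model."""
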