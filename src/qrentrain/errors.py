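"""Exception hierarchy shared across the pipeline."""


class QrentrainError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(QrentrainError):
    """A dialect/config file is missing or names a column that does not exist."""


class ValidationError(QrentrainError, ValueError):
    """Input data violates a domain invariant (bad row, bad link, bad value)."""


class StructuralError(QrentrainError):
    """Input files are internally inconsistent (e.g. mismatched frame counts)."""


class SegmentRangeError(QrentrainError):
    """A segment lies outside the span of the track or clip it indexes."""


class TooShortSegmentError(QrentrainError):
    """A segment covers fewer than two video frames; no displacement exists."""


class TrackRejectedError(QrentrainError):
    """Too many low-confidence frames (or none valid) to repair a track."""


class DegenerateModelError(QrentrainError):
    """A model cannot be fit (zero-variance predictor, non-nested comparison)."""


class ImputationError(QrentrainError):
    """A questionnaire item is missing for every respondent in the group."""
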