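"""Typed exceptions shared across the pipelines.

Every failure mode a caller may want to branch on has its own class; the
pipelines wrap stage failures in :class:`PipelineError` carrying the stage
name, so a batch runner can report *where* a recording failed rather than
just that it did.
"""


class ThermalVitalsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermalVitalsError):
    """Invalid parameter, band, sidecar key or config file."""


class FormatError(ThermalVitalsError):
    """A file exists but its contents violate the expected layout."""


class EmptySeriesError(FormatError):
    """A rate CSV contained a header but no data rows."""


class DegenerateInputError(ThermalVitalsError):
    """Input is structurally valid but carries no usable information
    (constant image, zero dynamic range, all-zero signal, too-short trace)."""


class SegmentationError(ThermalVitalsError):
    """Head/background segmentation produced an empty mask."""


class FeatureScarcityError(ThermalVitalsError):
    """No corner candidates survived selection inside the ROI."""


class TrackingFailureError(ThermalVitalsError):
    """All KLT points were lost before enough frames elapsed."""


class TrackingLossError(ThermalVitalsError):
    """ROI template tracking lost its target.

    Attributes
    ----------
    frame_index : int or None
        First frame at which the correlation peak fell below threshold.
    """

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class AlignmentError(ThermalVitalsError):
    """Two rate series share no overlapping time span."""


class DomainError(ThermalVitalsError):
    """A scalar argument is outside the mathematical domain (e.g. gt <= 0)."""


class PipelineError(ThermalVitalsError):
    """A pipeline stage failed; ``stage`` names the failing step."""

    def __init__(self, message: str, stage: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


class FusionDegenerateWarning(UserWarning):
    """Estimator fusion collapsed (all-zero posterior product); the
    autocorrelation posterior was used as a fallback."""
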