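"""Exception hierarchy shared across the pipeline."""


class ChewCountError(Exception):
    """Base class for all package errors."""


class InvalidInputError(ChewCountError):
    """Raised for empty or malformed inputs (e.g. an empty image)."""


class InvalidRectError(ChewCountError):
    """Raised when a rectangle falls outside the image bounds."""


class BackendError(ChewCountError):
    """Raised when a detection backend fails on a frame."""


class ConfigurationError(ChewCountError):
    """Raised for missing or inconsistent configuration (e.g. no jaw-index map)."""


class MissingSampleError(ChewCountError):
    """Raised when a per-frame quantity is requested from an invalid frame."""


class UnusableTrackError(ChewCountError):
    """Raised when too few frames of a track carry valid detections."""


class InvalidSpecError(ChewCountError):
    """Raised for infeasible filter/decomposition specifications."""


class NoPeaksError(ChewCountError):
    """Raised when an adaptive threshold is requested with no candidate peaks."""


class InsufficientDataError(ChewCountError):
    """Raised when an agreement statistic needs more data points."""


class UndefinedMetricError(ChewCountError):
    """Raised when a metric is undefined (e.g. MAPE with a zero reference count)."""
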