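"""Exception hierarchy for the pipeline.

All configuration and input problems raise subclasses of
:class:`SpinesyncError` so callers can catch pipeline failures as a group.
"""


class SpinesyncError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(SpinesyncError, ValueError):
    """A configuration value is missing, non-finite, or out of range."""


class InsufficientDataError(SpinesyncError, ValueError):
    """Too few frames / samples / groups for the requested operation."""


class EstimationFailedError(SpinesyncError, RuntimeError):
    """Baseline estimation could not find enough quiet frames."""


class InvalidRoiError(SpinesyncError, ValueError):
    """ROI masks are empty, out of bounds, or overlap where forbidden."""


class IncompatibleInputsError(SpinesyncError, ValueError):
    """Inputs that must share shape / frame interval / length do not."""


class EmptySelectionError(SpinesyncError, ValueError):
    """A selection (e.g. pairs within a radius) matched nothing."""


class UndefinedFitError(SpinesyncError, ValueError):
    """A regression/correlation fit is undefined (degenerate variance)."""


class MissingArtifactError(SpinesyncError, FileNotFoundError):
    """A pipeline stage requires an artifact a previous stage did not write."""
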