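"""Exception hierarchy for the gaitstab package."""


class GaitStabError(Exception):
    """Base class for all package-specific errors."""


class MissingMarkerError(GaitStabError):
    """A required marker is absent from a trial.

    Parameters
    ----------
    missing : list of str
        Canonical names of the absent markers.
    """

    def __init__(self, missing, message=None):
        self.missing = sorted(missing)
        super().__init__(message or f"missing required markers: {', '.join(self.missing)}")


class TrialFormatError(GaitStabError):
    """A marker file could not be parsed or is internally inconsistent."""


class DegeneratePoseError(GaitStabError):
    """Pelvis markers are (near-)collinear so no rigid-body frame exists."""

    def __init__(self, frame_index, message=None):
        self.frame_index = frame_index
        super().__init__(message or f"degenerate pelvis marker configuration at frame {frame_index}")


class EventDetectionError(GaitStabError):
    """No gait events could be detected in the trial."""


class SignalLengthError(GaitStabError):
    """A signal is too short for the requested operation."""


class ZeroVarianceError(GaitStabError):
    """A feature column has zero variance and cannot be standardized."""

    def __init__(self, column, message=None):
        self.column = column
        super().__init__(message or f"zero-variance feature column: {column}")


class RankExhaustedError(GaitStabError):
    """Deflation exhausted the data rank before reaching the requested
    number of components."""

    def __init__(self, achieved, requested, message=None):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            message
            or f"rank exhausted after {achieved} components (requested {requested})"
        )


class ConfigError(GaitStabError):
    """Invalid pipeline configuration."""
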