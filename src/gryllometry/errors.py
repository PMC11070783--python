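"""Exception hierarchy used across the package."""


class GryllometryError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GryllometryError):
    """A pose table does not conform to the expected DeepLabCut dialect."""


class PoseParseError(FormatError):
    """A cell in a pose table could not be parsed as a number."""


class ConfigurationError(GryllometryError):
    """A recording configuration is invalid or does not cover the data."""


class UnrecoverableTrackError(GryllometryError):
    """A bodypart has no valid observations and cannot be imputed."""


class DegenerateGeometryError(GryllometryError):
    """Keypoint geometry is degenerate (e.g. zero-length leg vector)."""


class DegenerateDataError(GryllometryError):
    """A statistic is undefined for the given data (e.g. zero variance)."""
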