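"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`SpeechManifoldError` so callers can catch
pipeline failures with a single except clause while still distinguishing
configuration mistakes from data problems.
"""


class SpeechManifoldError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpeechManifoldError, ValueError):
    """A parameter combination violates a documented precondition."""


class InvalidInputError(SpeechManifoldError, ValueError):
    """Input data has the wrong shape, range, or normalization."""


class FormatError(SpeechManifoldError, IOError):
    """A file could not be parsed in the expected on-disk format."""


class DegenerateDataError(SpeechManifoldError, ValueError):
    """Data is constant or otherwise carries no usable variation."""


class InsufficientDataError(SpeechManifoldError, ValueError):
    """Fewer exemplars are available than the analysis requires."""


class DegenerateGeometryError(SpeechManifoldError, ValueError):
    """A manifold collapsed onto another so capacity is undefined."""


class EmptySubsetError(SpeechManifoldError, ValueError):
    """A filter left no records to summarize."""


class OutOfRangeError(SpeechManifoldError, RuntimeError):
    """A bisection target was never bracketed; carries the observed curve."""

    def __init__(self, message, curve=None):
        super().__init__(message)
        self.curve = curve
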