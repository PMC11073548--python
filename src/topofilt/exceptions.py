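"""Exception hierarchy shared across the package."""


class TopofiltError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(TopofiltError, ValueError):
    """A parameter is outside its documented domain (non-finite, wrong sign, ...)."""


class IncompatibleNetworksError(TopofiltError, ValueError):
    """Two networks cannot be compared (unequal node counts or diagram sizes)."""


class DegenerateGroupingError(TopofiltError, ValueError):
    """A group has too few members for the requested statistic."""


class DegenerateDistanceError(TopofiltError, ValueError):
    """All relevant distances vanish; the statistic is undefined."""


class InsufficientSampleError(TopofiltError, ValueError):
    """Too few subjects for the requested resampling scheme."""


class FormatError(TopofiltError, ValueError):
    """An input file could not be parsed or failed validation."""


class ConfigError(TopofiltError, ValueError):
    """A run configuration is invalid or references missing paths."""
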