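"""Exception hierarchy for the adaptscape pipeline."""


class AdaptscapeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AdaptscapeError, ValueError):
    """A parameter violates its documented domain (negative radius, n < 1, ...)."""


class CoRegistrationError(AdaptscapeError, ValueError):
    """Grids that must share shape / cell size do not."""


class FormatError(AdaptscapeError, ValueError):
    """A raster or table file failed to parse; the message names the offending field."""


class TilingError(AdaptscapeError, ValueError):
    """Fine-grid dimensions are not divisible by the aggregation factor."""


class EmptyDomainError(AdaptscapeError, ValueError):
    """A scenario needs focal cells (e.g. PA cells) and the landscape has none."""


class DegenerateInputError(AdaptscapeError, ValueError):
    """An operation cannot proceed on this input (e.g. normalizing an all-zero grid)."""


class ConfigError(AdaptscapeError, ValueError):
    """A run configuration is missing or inconsistent; the message names the key."""
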