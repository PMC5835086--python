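"""Exception types raised by the pipeline."""


class SoabciError(Exception):
    """Base class for package errors."""


class InvalidSoaError(SoabciError, ValueError):
    """SOA too short: the 100-ms sound would overrun the stimulus interval."""


class UndefinedIntervalError(SoabciError, ValueError):
    """No block contains two targets, so no target-to-target interval exists."""


class InvalidFilterError(SoabciError, ValueError):
    """Band-pass cutoffs outside (0, Nyquist) or inverted."""


class EdgeEpochError(SoabciError, ValueError):
    """An event lies too close to the recording edge to extract its epoch."""


class InvalidLengthError(SoabciError, ValueError):
    """Epoch too short for the requested decimation factor."""


class MissingClassError(SoabciError, ValueError):
    """An epoch set lacks target or non-target epochs."""


class InsufficientPairsError(SoabciError, ValueError):
    """Fewer than two participants supplied to a paired test."""


class UndefinedCorrelationError(SoabciError, ValueError):
    """A correlation input has zero variance."""


class SingularMatrixError(SoabciError, ValueError):
    """Within-class scatter is singular and lambda = 0; use lambda > 0."""


class StratificationError(SoabciError, ValueError):
    """Cross-validation folds cannot be formed with both classes present."""


class FoldError(SoabciError, ValueError):
    """Too few trials per target direction to build the requested folds."""


class GroupingError(SoabciError, ValueError):
    """n-trial averaging requested with fewer than n trials available."""


class ConfigError(SoabciError, ValueError):
    """Invalid study configuration."""
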