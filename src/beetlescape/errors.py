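"""Exception hierarchy for beetlescape."""


class BeetlescapeError(Exception):
    """Base class for all package errors."""


class ConfigError(BeetlescapeError):
    """Invalid configuration: unknown key, bad type, or out-of-range value."""


class InvalidInputError(BeetlescapeError):
    """A runtime input (climate value, series, grid) is invalid."""


class InvalidArgumentError(BeetlescapeError):
    """An operation was called with inconsistent arguments."""


class UndefinedDistributionError(BeetlescapeError):
    """A diversity index was requested for an all-zero weight vector."""


class UndefinedLandscapeError(BeetlescapeError):
    """A landscape-level statistic is undefined (e.g. no trees anywhere)."""


class SimulationInvariantError(BeetlescapeError):
    """An internal invariant was violated during a simulation run."""
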