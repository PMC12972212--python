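"""Exception hierarchy for betaclock."""


class BetaClockError(Exception):
    """Base class for all betaclock errors."""


class InvalidConfigError(BetaClockError, ValueError):
    """A configuration object violates its invariants."""


class ValidationError(BetaClockError, ValueError):
    """Input data violates a structural or range constraint."""


class InsufficientDataError(BetaClockError, ValueError):
    """Too few observations to carry out the requested fit."""


class DegenerateDataError(BetaClockError, ValueError):
    """Data degenerate for the requested operation (e.g. all x identical)."""


class InfeasibleMomentsError(BetaClockError, ValueError):
    """(mean, variance) pair outside the feasible region of a Beta law."""


class NoOverlapError(BetaClockError, ValueError):
    """A sample shares no usable CpG site with the reference matrix."""


class CohortSizeError(BetaClockError, ValueError):
    """An age cohort is empty or below the minimum training size."""


class ModelSchemaError(BetaClockError, ValueError):
    """A serialized model has an unknown format or schema version."""
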