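"""Exception hierarchy shared by all optorc modules."""


class OptorcError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(OptorcError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateDataError(OptorcError):
    """The input is formally valid but carries no usable variation
    (e.g. zero variance, pooled proportion of 0 or 1)."""


class EmptyResultError(OptorcError):
    """An operation produced no usable output (e.g. zero usable events)."""


class NotFoundError(OptorcError):
    """A requested feature (e.g. a deceleration onset) does not exist
    in the data."""


class SimulationError(OptorcError):
    """The stochastic simulation hit a non-finite hazard; the message
    names the offending time bin."""


class FitFailureError(OptorcError):
    """A least-squares fit could not be performed (too few bins,
    no drive variation, or optimizer failure)."""


class PipelineError(OptorcError):
    """A pipeline stage failed; the message names the stage."""
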