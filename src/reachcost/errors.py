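"""Exception types shared across the pipeline."""


class ReachCostError(Exception):
    """Base class for all package-specific errors."""


class InvalidTargetError(ReachCostError, ValueError):
    """A target angle outside the four canonical positions."""


class ScheduleInfeasibleError(ReachCostError):
    """Trial-order constraints could not be satisfied within the retry budget."""


class PreconditionError(ReachCostError, ValueError):
    """An operation's documented precondition was violated by the input."""


class NoMovementError(ReachCostError):
    """The hand never left the start circle."""


class NoStopError(ReachCostError):
    """Speed never fell below the stop threshold after movement onset."""


class InsufficientTraceError(ReachCostError):
    """The trace ends before the sample the operation needs."""


class InconsistentEventsError(ReachCostError):
    """Detected kinematic events are out of order (e.g. end before onset)."""


class IncomparableModelsError(ReachCostError):
    """Model fits with different responses cannot be ranked by AIC."""
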