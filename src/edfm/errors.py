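"""Exception types shared across the package."""


class EDFMError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(EDFMError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateChannelError(EDFMError, ValueError):
    """A data channel is constant and cannot be z-scored."""


class AllocationError(EDFMError, ValueError):
    """Assimilate allocation is undefined (all sink strengths zero)."""


class UndefinedMetricError(EDFMError, ValueError):
    """A metric's denominator is degenerate (constant or zero-mean obs)."""


class FitError(EDFMError, RuntimeError):
    """A least-squares or nonlinear fit failed to produce a usable result."""
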