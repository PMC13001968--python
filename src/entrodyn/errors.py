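"""Exception hierarchy shared across the package."""


class EntrodynError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(EntrodynError, ValueError):
    """Raised when an input violates a documented precondition."""


class SchemaError(InvalidInputError):
    """Raised when a file does not match the expected tabular schema."""


class AlignmentError(InvalidInputError):
    """Raised when entropy series do not share a common wave grid."""


class SimulationError(EntrodynError, RuntimeError):
    """Raised when the ODE integrator fails or the state blows up.

    Carries ``t`` and ``state`` diagnostics when available.
    """

    def __init__(self, message, t=None, state=None):
        super().__init__(message)
        self.t = t
        self.state = state


class FitError(EntrodynError, RuntimeError):
    """Raised when every start of a multistart fit fails."""


class UndefinedMetricError(InvalidInputError):
    """Raised when a metric is undefined (e.g. constant observations)."""
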