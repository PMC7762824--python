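"""Shared exception types."""


class TcmodelError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TcmodelError, ValueError):
    """A parameter value violates its physical constraint (e.g. dispersion <= 0)."""


class StructuralError(TcmodelError, ValueError):
    """Shapes, masks or state vectors do not match the circuit structure."""


class NumericalError(TcmodelError, ArithmeticError):
    """Non-finite values encountered where finite ones are required."""


class InstabilityError(TcmodelError, RuntimeError):
    """Numerical integration diverged (membrane potential out of range).

    Carries the offending parameter vector for diagnosis.
    """

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


class DegenerateDelayError(TcmodelError, ValueError):
    """The delay operator I - D*J is singular; reduce delays or time step."""
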