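"""Package-wide exception types."""


class FlowscalesError(Exception):
    """Base class for errors raised by flowscales."""


class InvalidParameterError(FlowscalesError, ValueError):
    """A parameter violates a documented precondition."""


class MalformedRecordsError(FlowscalesError, ValueError):
    """Input OD records could not be parsed; carries offending line numbers."""

    def __init__(self, message: str, lines: list[int] | None = None):
        super().__init__(message)
        self.lines = lines or []


class NumericalError(FlowscalesError, RuntimeError):
    """A numerical computation failed beyond tolerance (e.g. singular solve)."""


class UndefinedStatisticError(FlowscalesError, ValueError):
    """A statistic is undefined for the given input (e.g. zero-variance R^2)."""
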