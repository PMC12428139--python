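"""Exception hierarchy shared across the package.

CLI exit-code convention: validation / design / configuration problems map to
exit code 2, optimizer non-convergence to exit code 3.
"""


class EnzkinError(Exception):
    """Base class for all package errors."""


class ValidationError(EnzkinError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(EnzkinError):
    """A configuration file or mapping is incomplete or inconsistent."""


class DesignError(EnzkinError):
    """An experimental design cannot support the requested analysis."""


class InfeasibilityError(EnzkinError):
    """A constraint (e.g. target ionic strength) cannot be satisfied."""

    def __init__(self, message: str, excess: float | None = None):
        super().__init__(message)
        self.excess = excess


class ConvergenceError(EnzkinError):
    """The optimizer failed on every start; carries the best attempt."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


class UsageError(EnzkinError):
    """An API contract violation (e.g. mixing incompatible results)."""


class ParseError(EnzkinError):
    """A data file could not be parsed; message names the column/row."""
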