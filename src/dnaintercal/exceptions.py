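"""Exception hierarchy shared by all analysis modules."""


class DnaIntercalError(Exception):
    """Base class for all package errors."""


class InvalidInputError(DnaIntercalError, ValueError):
    """Input violates a documented precondition (bad concentration, units, ...)."""


class InsufficientDataError(DnaIntercalError, ValueError):
    """Too few usable observations to attempt a fit."""


class NonBindingSignalError(DnaIntercalError, ValueError):
    """Regression produced a non-positive slope/intercept: no binding signal."""


class DegenerateModelError(DnaIntercalError, ValueError):
    """Model parameters make the observable insensitive (e.g. eps_b == eps_f)."""


class DegenerateGeometryError(DnaIntercalError, ValueError):
    """Atom selection is collinear or otherwise geometrically degenerate."""


class FitFailureError(DnaIntercalError, RuntimeError):
    """Iterative optimisation failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConnectivityError(DnaIntercalError, ValueError):
    """Adjacent umbrella windows do not overlap; names the offending gap."""


class ConfigError(DnaIntercalError, ValueError):
    """Pipeline configuration failed schema validation."""
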