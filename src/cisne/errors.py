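"""Exception hierarchy shared across the package."""


class CisneError(Exception):
    """Base class for all package-specific errors."""


class DomainError(CisneError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(CisneError, ValueError):
    """Input data violates a dataset invariant."""


class FitInfeasibleError(CisneError):
    """Too few usable observations to attempt a fit."""


class DegenerateFitError(CisneError):
    """The fit is formally computable but yields invalid parameters
    (e.g. non-positive slope in the linearized regression, or constant
    response data)."""


class FitFailureError(CisneError):
    """The nonlinear optimizer failed to converge after all fallback
    restarts. Carries per-restart diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class UsageError(CisneError, ValueError):
    """An operation was called in a way its contract does not allow."""
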