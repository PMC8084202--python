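"""Exception hierarchy shared across the package."""


class MrTauError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MrTauError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(MrTauError, ValueError):
    """Input data cannot be coerced into the trial-structured format."""


class DegenerateDataError(MrTauError, ValueError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class SingleTrialError(MrTauError, ValueError):
    """An operation requires a trial structure with at least two trials."""


class FitFailureError(MrTauError, RuntimeError):
    """The optimizer failed to converge from every initial guess."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
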