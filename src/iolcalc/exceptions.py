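"""Exception and warning types shared across the package."""


class IolcalcError(Exception):
    """Base class for all package errors."""


class DomainError(IolcalcError, ValueError):
    """An input is outside the mathematical or physiological domain of an operation."""


class ValidationError(IolcalcError, ValueError):
    """A record violates a data-model invariant (message names the eye and field)."""


class FormatError(IolcalcError, ValueError):
    """A file does not conform to the expected tabular schema."""


class DegenerateGeometryError(IolcalcError, ArithmeticError):
    """An optical vergence expression is singular for the supplied eye geometry."""


class ConvergenceError(IolcalcError, RuntimeError):
    """A root-finding step failed to bracket or converge."""


class CollinearityError(IolcalcError, ValueError):
    """Regressors are (numerically) collinear; a regression fit is not identifiable."""


class BackSolveError(IolcalcError, ArithmeticError):
    """No physiologically plausible effective lens position explains an observed outcome."""


class ClampWarning(UserWarning):
    """A corneal-height square root was clamped at its geometric limit."""
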