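"""Exception hierarchy for wpbribbon."""


class WpbRibbonError(Exception):
    """Base class for all wpbribbon errors."""


class ValidationError(WpbRibbonError, ValueError):
    """Input violates a documented invariant (probabilities, weights, schemas)."""


class EmptyInputError(WpbRibbonError, ValueError):
    """An operation that requires at least one record received none."""


class DegenerateParameterError(ValidationError):
    """A parameter value at which the model has no finite / well-defined output."""


class UnfittableError(WpbRibbonError, ValueError):
    """The observed distribution carries no information about the parameter."""


class ConvergenceError(WpbRibbonError, RuntimeError):
    """A numerical procedure failed to reach its stated tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual
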