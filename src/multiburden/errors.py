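"""Exception hierarchy shared across the package."""


class MultiburdenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MultiburdenError):
    """A line of an input file could not be parsed; the message names the line."""


class ValidationError(MultiburdenError):
    """Parsed content violates a format invariant (e.g. duplicate IDs)."""


class DataError(MultiburdenError):
    """Inputs are individually well-formed but mutually inconsistent."""


class UsageError(MultiburdenError):
    """Bad command-line arguments or an invalid analysis request."""


class RegionSkipped(MultiburdenError):
    """A region cannot be analysed; carries the human-readable reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class SingularModelError(MultiburdenError):
    """The weighted cross-product matrix is singular (collinear predictors)."""


class DegenerateVarianceError(MultiburdenError):
    """The residual variance estimate is (numerically) zero.

    The normal-equations solution is still well defined; the coefficient
    estimates are attached so callers can report them if useful.
    """

    def __init__(self, message: str, alpha=None, betas=None):
        super().__init__(message)
        self.alpha = alpha
        self.betas = betas


class GeneratorError(MultiburdenError):
    """A simulation specification is infeasible."""
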