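"""Exception hierarchy shared across fermkin modules."""


class FermkinError(Exception):
    """Base class for all fermkin-specific errors."""


class SchemaError(FermkinError, ValueError):
    """A table is missing required columns or has the wrong shape."""


class DataValidationError(FermkinError, ValueError):
    """A table parsed but violates a domain invariant (e.g. negative SD)."""


class FitConvergenceError(FermkinError, RuntimeError):
    """A nonlinear fit failed to converge after bounded restarts.

    Carries the best iterate found so far in ``best`` (may be None).
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateModelError(FermkinError, ValueError):
    """Model parameters describe a degenerate curve (e.g. zero rise)."""


class RankDeficiencyError(FermkinError, ValueError):
    """A design matrix is rank deficient; names the collinear columns."""

    def __init__(self, message, collinear_terms=()):
        super().__init__(message)
        self.collinear_terms = tuple(collinear_terms)


class DegenerateVarianceError(FermkinError, ValueError):
    """A variance-based statistic is undefined (zero corrected sum of squares)."""
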