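"""Named exceptions raised across the package.

Every contract violation surfaces as one of these (all derive from
:class:`FsvmsrError`) so callers and the CLI can distinguish user errors
from bugs.
"""


class FsvmsrError(Exception):
    """Base class for all package errors."""


class MissingLabelColumnError(FsvmsrError):
    """The requested label column is not in the CSV header."""


class NonNumericFeatureError(FsvmsrError):
    """A feature cell could not be parsed as a number (names row/column)."""


class MissingValueError(FsvmsrError):
    """A feature cell is empty/NaN under the rejection policy."""


class TooFewSamplesError(FsvmsrError):
    """Fewer than two samples, or fewer than an operation requires."""


class UnknownLevelError(FsvmsrError):
    """A risk level outside the grouping scheme's domain."""


class DimensionMismatchError(FsvmsrError):
    """Incompatible array shapes between fitted object and input."""


class InvalidParameterError(FsvmsrError):
    """A hyperparameter outside its documented range (e.g. gamma <= 0)."""


class ZeroDegreeError(FsvmsrError):
    """A similarity-graph vertex with zero degree; the normalized Laplacian
    is undefined."""


class SylvesterSolveError(FsvmsrError):
    """The Sylvester solver failed or returned a solution above the residual
    tolerance; usually cured by a positive ridge."""


class SingleClassError(FsvmsrError):
    """A binary subproblem with only one effective class (after membership
    zeros are excluded)."""


class ConvergenceError(FsvmsrError):
    """SMO did not reach the KKT tolerance within max_iter."""


class EmptyClassError(FsvmsrError):
    """A class required by the operation has no members."""


class CorrelationInfeasibleError(FsvmsrError):
    """A target feature-label correlation unattainable for a binary feature
    at its prevalence."""


class DegenerateStatisticError(FsvmsrError):
    """A statistic is undefined on the given inputs (e.g. single-class ROC)."""
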