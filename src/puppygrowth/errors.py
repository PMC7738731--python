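"""Exception hierarchy for puppygrowth.

Everything derives from :class:`PuppyGrowthError` so callers (and the CLI)
can catch package failures in one place; argument-validation failures also
derive from :class:`ValueError` so they behave like ordinary Python misuse.
"""


class PuppyGrowthError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(PuppyGrowthError, ValueError):
    """An argument violates a documented precondition."""


class UnreachableTargetError(PuppyGrowthError):
    """A weight multiple lies above the maximum the growth curve can reach."""


class UnderdeterminedFitError(PuppyGrowthError):
    """A puppy has too few records for the requested polynomial order."""


class SingularFitError(PuppyGrowthError):
    """The regression design matrix is rank deficient."""


class SelectionFailureError(PuppyGrowthError):
    """No polynomial order passed the coefficient-significance gate."""

    def __init__(self, message, comparison=None):
        super().__init__(message)
        self.comparison = comparison


class InsufficientDataError(PuppyGrowthError):
    """Too few records for the requested estimate."""


class UnsegmentableError(PuppyGrowthError):
    """No growth-curve segment could be formed from a weight series."""


class InsufficientGroupError(PuppyGrowthError):
    """A comparison group has fewer members than the test requires."""


class ConfigError(PuppyGrowthError):
    """A simulation configuration is inconsistent or infeasible."""


class DatasetError(PuppyGrowthError, ValueError):
    """A weight-record table failed parsing or validation."""
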