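"""Exception hierarchy for the affiliation-exposure pipeline."""


class AffilexError(Exception):
    """Base class for all package errors."""


class SchemaError(AffilexError):
    """A corpus file is missing a required column or key."""


class VocabularyError(AffilexError):
    """A label token is outside a closed vocabulary."""


class ConfigError(AffilexError):
    """A generator or run configuration is invalid."""


class EmptyNetworkError(AffilexError):
    """A theme has no affiliated users, or a count matrix is all zero."""


class DesignError(AffilexError):
    """The regression design matrix is rank deficient."""


class ConvergenceError(AffilexError):
    """The profile-likelihood optimizer failed to converge.

    Carries the profile trace (list of (rho, loglik) pairs) for diagnostics.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SingularityError(AffilexError):
    """rho is at or beyond an admissible-interval endpoint, so I - rho*W is singular."""
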