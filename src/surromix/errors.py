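"""Exception types shared across surromix modules."""


class SurromixError(Exception):
    """Base class for all surromix errors."""


class SingularDesignError(SurromixError):
    """Raised when a (weighted) least-squares design matrix is rank deficient."""


class DegenerateEMError(SurromixError):
    """Raised when every EM initialization collapses (empty component or floored variance)."""


class ConcordanceUndefinedError(SurromixError):
    """Raised when concordance is requested but every outcome value is tied."""


class InsufficientDataError(SurromixError):
    """Raised when too few (observed) rows are available for a fit."""


class PerfectSeparationError(SurromixError):
    """Raised when the propensity logistic model separates perfectly.

    Remedy: drop or coarsen the offending covariate, or penalize the fit.
    """
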