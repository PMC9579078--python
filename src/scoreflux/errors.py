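"""Exception hierarchy."""


class ScorefluxError(Exception):
    """Base class for all package errors."""


class DataError(ScorefluxError):
    """Invalid response or covariate data (missing cells, out-of-range codes, ...)."""


class EstimationError(ScorefluxError):
    """Model cannot be estimated from the given data (e.g. an item without variance)."""


class SingularCovarianceError(ScorefluxError):
    """The score covariance matrix is numerically singular.

    Usually a sign of an identification problem; testing a parameter subset
    (``pars``) with a nonsingular covariance is the recommended way out.
    """


class UsageError(ScorefluxError):
    """Incompatible arguments, e.g. a statistic paired with the wrong covariate kind."""


class ConfigError(ScorefluxError):
    """Malformed configuration or simulation design."""


class StudyError(ScorefluxError):
    """A simulation study could not produce any usable replication."""


class ConvergenceWarning(UserWarning):
    """Estimation stopped at the iteration limit before meeting the tolerance."""
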