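"""Exception types shared across the package."""


class MMRiskError(Exception):
    """Base class for all package errors."""


class ConfigError(MMRiskError, ValueError):
    """Invalid simulation or run configuration."""


class CohortFormatError(MMRiskError, ValueError):
    """A cohort file violates the documented on-disk format."""


class MissingColumnError(CohortFormatError):
    """A required column is absent from a clinical or survival table."""


class DuplicatePatientError(CohortFormatError):
    """The same patient id appears more than once within one cohort file."""


class NonNumericExpressionError(CohortFormatError):
    """An expression matrix cell could not be parsed as a number."""


class InvalidISSError(CohortFormatError):
    """ISS stage outside {1, 2, 3}."""


class NegativeTimeError(CohortFormatError):
    """A survival or censoring time is negative."""


class PatientMismatchError(CohortFormatError):
    """Patient ids disagree between the expression, clinical and survival files."""


class DegenerateFeatureError(MMRiskError, ValueError):
    """A model feature is constant (or otherwise uninformative) across patients."""


class ConvergenceError(MMRiskError, RuntimeError):
    """Cox partial-likelihood maximization failed to converge.

    Carries ``diagnostics``: iteration count, last log-likelihood, max |beta|.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UndefinedMetricError(MMRiskError, ValueError):
    """A metric is undefined on the given data (e.g. an empty outcome class)."""


class MissingPredictionError(MMRiskError, ValueError):
    """An evaluable patient has no risk prediction."""
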