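"""Exception hierarchy shared across the package."""


class CohortCEAError(Exception):
    """Base class for all package errors."""


class ModelValidationError(CohortCEAError, ValueError):
    """An input violates a structural invariant (simplex, range, schema)."""


class ConfigurationError(CohortCEAError, ValueError):
    """A model/run configuration value is out of its admissible range."""


class UndefinedICERError(CohortCEAError, ValueError):
    """ICER requested for a pair with zero effect difference.

    Carries the sign of the cost difference so callers can still report
    the cost side of the comparison.
    """

    def __init__(self, message: str, delta_cost: float):
        super().__init__(message)
        self.delta_cost = delta_cost


class InfeasibleMomentsError(CohortCEAError, ValueError):
    """Requested (mean, SE) pair admits no distribution of the given family."""


class SamplingInfeasibleError(CohortCEAError, RuntimeError):
    """Rejection sampling exhausted its attempt budget."""
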