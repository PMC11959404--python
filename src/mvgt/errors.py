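"""Exception hierarchy shared across the pipeline stages."""


class MvgtError(Exception):
    """Base class for all package-specific errors."""


class TableValidationError(MvgtError):
    """An assessment table violates its schema or scale constraints."""


class NotPositiveSemidefiniteError(MvgtError):
    """A ground-truth covariance matrix is not PSD after symmetrization."""

    def __init__(self, effect: str, min_eigenvalue: float):
        self.effect = effect
        self.min_eigenvalue = min_eigenvalue
        super().__init__(
            f"covariance matrix for effect '{effect}' is not positive "
            f"semidefinite (smallest eigenvalue {min_eigenvalue:.3e})"
        )


class DesignInfeasibleError(MvgtError):
    """Filtering emptied the design; ``stage`` names the filter responsible."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"design infeasible at '{stage}': {message}")


class UnbalancedDesignError(MvgtError):
    """Balanced estimator called on a non-crossed table."""


class IdentifiabilityError(MvgtError):
    """The design cannot separate the requested variance components."""


class ConvergenceError(MvgtError):
    """Iterative variance-component estimation failed to converge."""

    def __init__(self, message: str, trace=None):
        self.trace = trace if trace is not None else []
        super().__init__(message)


class UndefinedStatisticError(MvgtError):
    """A ratio statistic has a zero denominator (e.g. zero total variance)."""
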