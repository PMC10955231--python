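"""Exception hierarchy for the package."""


class DabePbpkError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DabePbpkError, ValueError):
    """A scalar parameter violates its physical constraint (e.g. t1/2 <= 0)."""


class InvalidDataError(DabePbpkError, ValueError):
    """An input dataset is unusable (all-zero, non-monotone times, ...)."""


class EstimationError(DabePbpkError, RuntimeError):
    """Nonlinear estimation failed to converge.

    Carries the last objective value seen by the optimizer.
    """

    def __init__(self, message, last_objective=None):
        super().__init__(message)
        self.last_objective = last_objective


class ConfigurationError(DabePbpkError, ValueError):
    """A model configuration is internally inconsistent (unknown product id,
    routing cycle, missing physiology field, unsupported route, ...)."""


class ComparisonError(DabePbpkError, ValueError):
    """Two simulation results are not comparable (mismatched regimens)."""


class SolverError(DabePbpkError, RuntimeError):
    """ODE integration failed; carries diagnostic context."""

    def __init__(self, message, t_failure=None):
        super().__init__(message)
        self.t_failure = t_failure


class UndefinedMetricError(DabePbpkError, ZeroDivisionError):
    """A summary metric is undefined (e.g. Fg when nothing was absorbed)."""
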