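"""Exception types shared across the pipeline."""


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class SolverError(RuntimeError):
    """A nonlinear solver or integrator failed to converge."""


class StabilityError(RuntimeError):
    """A steady state is marginal: an eigenvalue real part sits inside the
    classification margin, so stable/unstable cannot be decided."""


class NormalizationError(ValueError):
    """Reference-gene normalization cannot be performed (e.g. zero reference)."""


class VarianceError(ValueError):
    """An oxygen level lacks the replication or variance the objective needs."""


class FitError(RuntimeError):
    """Curve fitting failed or the data are degenerate."""
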