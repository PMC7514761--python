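"""Exception hierarchy for auxsel."""


class AuxselError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AuxselError, ValueError):
    """Parameter vector violates its constraints (e.g. covariance not PD)."""


class DataError(AuxselError, ValueError):
    """Input data violates a contract (bad latent labels, ragged columns, ...)."""


class FitDegenerateError(AuxselError, RuntimeError):
    """Every EM restart collapsed onto the likelihood-degeneracy floor."""


class SingularInformationError(AuxselError, RuntimeError):
    """Estimated information matrix is numerically singular.

    Carries the offending condition number in ``cond``.
    """

    def __init__(self, cond: float, message: str | None = None):
        self.cond = float(cond)
        super().__init__(
            message or f"information matrix numerically singular (cond={cond:.3e})"
        )


class BoundaryDerivativeError(AuxselError, RuntimeError):
    """A finite-difference step cannot stay inside the parameter space."""


class EvaluationError(AuxselError, RuntimeError):
    """A numerical evaluation (e.g. quadrature) produced a non-finite result."""


class LoocvError(AuxselError, RuntimeError):
    """Too many leave-one-out refits failed to converge."""
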