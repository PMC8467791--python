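"""Exception hierarchy shared by all pipeline stages."""


class OculostopError(Exception):
    """Base class for all package errors."""


class InvalidInputError(OculostopError, ValueError):
    """An argument violates a documented precondition."""


class StabilityError(OculostopError):
    """A neural parameter set yields an unstable (non-decaying) system."""

    def __init__(self, max_real_eigenvalue: float):
        self.max_real_eigenvalue = float(max_real_eigenvalue)
        super().__init__(
            f"unstable connectivity: largest Jacobian eigenvalue real part "
            f"{self.max_real_eigenvalue:+.4f} >= 0"
        )


class DependencyError(OculostopError):
    """A pipeline stage is missing the outputs of an upstream stage."""
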