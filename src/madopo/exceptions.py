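"""Exception hierarchy for madopo."""


class MadopoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MadopoError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateGeometryError(MadopoError, ValueError):
    """Geometric input is degenerate (e.g. collinear landmark set)."""


class AlignmentError(MadopoError, ValueError):
    """Field maps / sensor arrays do not share the same channel key set."""


class SingularityError(MadopoError, ArithmeticError):
    """Field evaluation requested at (or numerically on top of) a source."""


class DetectionError(MadopoError, RuntimeError):
    """Pulse detection failed; carries a diagnostic SNR estimate."""

    def __init__(self, message: str, snr_estimate: float | None = None):
        super().__init__(message)
        self.snr_estimate = snr_estimate


class FitError(MadopoError, RuntimeError):
    """An inverse fit produced no usable candidate."""


class IdentifiabilityError(FitError):
    """The supplied measurements cannot constrain the requested parameter."""
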