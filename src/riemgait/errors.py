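"""Exception hierarchy shared across the pipeline."""


class RiemgaitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RiemgaitError):
    """A file violates the documented layout (missing columns, bad header...)."""


class ParseError(FormatError):
    """A cell or token could not be parsed; message carries the location."""


class UnsupportedFormatError(FormatError):
    """A file uses a dialect feature outside the supported subset."""


class DegenerateBoneError(RiemgaitError):
    """A bone has (near-)coincident endpoints in some frame."""


class UndefinedLogError(RiemgaitError):
    """Logarithm map requested at (near-)antipodal points."""


class InvalidTangentError(RiemgaitError):
    """A tangent vector is not orthogonal to its base point."""


class ConvergenceError(RiemgaitError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class NoPeriodicityError(RiemgaitError):
    """No usable peak in the speed autocorrelation profile."""


class TooShortError(RiemgaitError):
    """Sequence shorter than the minimum needed by an operation."""


class AlignmentError(RiemgaitError):
    """Time-warping produced a degenerate path."""


class DegenerateBandwidthError(RiemgaitError):
    """All feature vectors coincide; the RBF bandwidth would be zero."""


class WindowTooSmallError(RiemgaitError):
    """A covariance window holds fewer than two frames."""


class NotTrainedError(RiemgaitError):
    """A model method requires training that has not happened."""
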