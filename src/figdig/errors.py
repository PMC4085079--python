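"""Exception hierarchy for figure digitization failures."""


class FigdigError(Exception):
    """Base class for all figdig-specific errors."""


class CalibrationError(FigdigError):
    """A coordinate system cannot be built from the given calibration."""


class CollinearAxesError(CalibrationError):
    """The two axis vectors are (numerically) linearly dependent.

    The pixel-to-data transform decomposes a clicked pixel over the axis
    vectors; no solution exists when a1*b2 == a2*b1.
    """


class ZeroLengthAxisError(CalibrationError):
    """Both intercept pixels of an axis coincide, giving a zero vector."""


class DegenerateSpanError(CalibrationError):
    """The two intercept values of an axis are equal (zero data span)."""


class LogDomainError(CalibrationError):
    """A logarithmic y-axis requires strictly positive y values."""


class NotCapturingError(FigdigError):
    """A pixel was submitted while the session is not capturing."""


class MissingPixelError(FigdigError):
    """An edit action that needs a replacement pixel was given none."""


class SingularDistortionError(FigdigError):
    """A fixture distortion matrix is not invertible."""


class ParseError(FigdigError):
    """Malformed text input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None,
                 position: int | None = None):
        self.line = line
        self.position = position
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (
                f", position {position})" if position is not None else ")")
        super().__init__(message + loc)
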