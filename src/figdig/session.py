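"""Capture-session state machine.

A session records clicked pixels in order.  While calibration is
incomplete the first four captured pixels fill the intercept slots
``p1, p2, p3, p4`` (y-axis top, y-axis bottom, x-axis left, x-axis right);
every later pixel is a data click.  Only raw pixels are stored — data
coordinates are re-derived from the current calibration on every request,
so re-capturing the axes or changing axis values retroactively updates all
output without losing collected points.  When calibration is incomplete
the session falls back to emitting raw pixel coordinates so the user can
apply their own transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, TextIO, Tuple, Union

from .errors import MissingPixelError, NotCapturingError, ParseError
from .geometry import (
    AxisCalibration,
    CoordinateSystem,
    DataPoint,
    PixelLike,
    PixelPoint,
    YScale,
    as_pixel,
    build_coordinate_system,
)

__all__ = ["AxisValues", "CaptureSession", "DerivedOutput",
           "load_session", "parse_pixel_lines"]

EDIT_ACTIONS = ("insert", "delete", "overwrite")


@dataclass(frozen=True)
class AxisValues:
    """The four intercept values plus the y-scale flag.

    Ordered ``y2, y1, x1, x2`` to match the natural clicking path (top of
    the y-axis, down to the origin, out along the x-axis).
    """

    y2: float
    y1: float
    x1: float
    x2: float
    y_scale: YScale = "linear"


@dataclass(frozen=True)
class DerivedOutput:
    """Result of deriving a session's output.

    ``raw`` is True when calibration was incomplete and ``points`` holds
    the untransformed pixels instead of data coordinates.
    """

    points: Union[List[DataPoint], List[PixelPoint]]
    raw: bool


@dataclass
class CaptureSession:
    intercept_pixels: List[PixelPoint] = field(default_factory=list)
    axis_values: Optional[AxisValues] = None
    raw_points: List[PixelPoint] = field(default_factory=list)
    capturing: bool = False

    # -- capture control ------------------------------------------------
    def toggle_capturing(self) -> "CaptureSession":
        """Flip the capturing flag; clicks are rejected while off."""
        self.capturing = not self.capturing
        return self

    def add_pixel(self, p: PixelLike) -> "CaptureSession":
        """Record a click: intercept slots fill first, then data points."""
        if not self.capturing:
            raise NotCapturingError(
                "session is not capturing; call toggle_capturing() first")
        p = as_pixel(p)
        if len(self.intercept_pixels) < 4:
            self.intercept_pixels.append(p)
        else:
            self.raw_points.append(p)
        return self

    def set_axis_values(self, y2: float, y1: float, x1: float, x2: float,
                        y_scale: YScale = "linear") -> "CaptureSession":
        """Set or replace the intercept values; allowed at any time."""
        self.axis_values = AxisValues(float(y2), float(y1), float(x1),
                                      float(x2), y_scale)
        return self

    def reset_axes(self) -> "CaptureSession":
        """Clear the intercept pixels so the next four clicks redefine the
        axes.  Data points are retained and re-transformed under the new
        calibration."""
        self.intercept_pixels.clear()
        return self

    def new_dataset(self) -> "CaptureSession":
        """Discard collected data points; calibration stays intact."""
        self.raw_points.clear()
        return self

    # -- editing ---------------------------------------------------------
    def edit_point(self, action: str, index: int,
                   p: Optional[PixelLike] = None) -> "CaptureSession":
        """Insert, delete or overwrite the data point at ``index``.

        Indices are 0-based into the capture order; ``insert`` allows
        ``index == len(raw_points)`` (append).  Derived coordinates follow
        automatically since they are never cached.
        """
        if action not in EDIT_ACTIONS:
            raise ValueError(
                f"unknown edit action {action!r}; expected one of "
                f"{EDIT_ACTIONS}")
        n = len(self.raw_points)
        limit = n + 1 if action == "insert" else n
        if not 0 <= index < limit:
            raise IndexError(
                f"point index {index} out of range for {n} captured points")
        if action == "delete":
            del self.raw_points[index]
            return self
        if p is None:
            raise MissingPixelError(f"edit action {action!r} needs a pixel")
        p = as_pixel(p)
        if action == "insert":
            self.raw_points.insert(index, p)
        else:
            self.raw_points[index] = p
        return self

    # -- derivation -------------------------------------------------------
    @property
    def calibration_complete(self) -> bool:
        if len(self.intercept_pixels) != 4 or self.axis_values is None:
            return False
        try:
            self.coordinate_system()
        except Exception:
            return False
        return True

    def calibration(self) -> AxisCalibration:
        """The current calibration; requires 4 intercepts and axis values."""
        if len(self.intercept_pixels) != 4:
            raise ValueError(
                f"calibration incomplete: {len(self.intercept_pixels)}/4 "
                "intercept pixels captured")
        if self.axis_values is None:
            raise ValueError("calibration incomplete: axis values unset")
        v = self.axis_values
        p1, p2, p3, p4 = self.intercept_pixels
        return AxisCalibration(p1, p2, p3, p4, v.y2, v.y1, v.x1, v.x2,
                               v.y_scale)

    def coordinate_system(self) -> CoordinateSystem:
        return build_coordinate_system(self.calibration())

    def derive_output(self) -> DerivedOutput:
        """Transform all data clicks, or fall back to raw pixels.

        With a complete, valid calibration the raw points are mapped to
        data coordinates in capture order.  With an incomplete calibration
        every captured pixel (intercept slots included) is returned
        verbatim (``raw=True``), so the user can apply their own
        transform.  An invalid calibration (e.g. collinear axes) raises;
        the session is left unchanged.
        """
        if len(self.intercept_pixels) == 4 and self.axis_values is not None:
            from .geometry import pixel_to_data
            cs = self.coordinate_system()
            return DerivedOutput(
                [pixel_to_data(cs, p) for p in self.raw_points], raw=False)
        return DerivedOutput(list(self.intercept_pixels)
                             + list(self.raw_points), raw=True)

    # -- persistence ------------------------------------------------------
    def save(self, fh: TextIO) -> None:
        """Write the session as plain text; ``load_session`` restores it
        bit-exactly (floats rendered with repr precision)."""
        fh.write("# figdig session\n")
        if self.axis_values is not None:
            v = self.axis_values
            fh.write(f"axes: {v.y2!r} {v.y1!r} {v.x1!r} {v.x2!r} "
                     f"{v.y_scale}\n")
        fh.write(f"intercepts: {len(self.intercept_pixels)}\n")
        for p in list(self.intercept_pixels) + list(self.raw_points):
            fh.write(f"{p.col!r} {p.row!r}\n")


def parse_pixel_lines(lines, start_line: int = 1) -> List[PixelPoint]:
    """Parse "col row" pairs, skipping blank and '#' comment lines."""
    pixels = []
    for i, raw in enumerate(lines, start=start_line):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(
                f"expected 'col row' pair, got {text!r}", line=i)
        try:
            pixels.append(PixelPoint(float(parts[0]), float(parts[1])))
        except ValueError:
            raise ParseError(f"non-numeric pixel pair {text!r}", line=i)
    return pixels


def load_session(fh: TextIO) -> CaptureSession:
    """Read a session (or bare clicks) file.

    Accepts the full session dialect written by :meth:`CaptureSession.save`
    as well as a bare list of "col row" lines, in which case the first
    four pairs become the intercept pixels.
    """
    s = CaptureSession()
    body: List[Tuple[int, str]] = []
    n_intercepts: Optional[int] = None
    for i, raw in enumerate(fh, start=1):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        if text.startswith("axes:"):
            parts = text[len("axes:"):].split()
            if len(parts) != 5 or parts[4] not in ("linear", "log"):
                raise ParseError(
                    f"malformed axes header {text!r}", line=i)
            try:
                s.set_axis_values(*map(float, parts[:4]), y_scale=parts[4])
            except ValueError:
                raise ParseError(f"non-numeric axes header {text!r}", line=i)
            continue
        if text.startswith("intercepts:"):
            try:
                n_intercepts = int(text[len("intercepts:"):].strip())
            except ValueError:
                raise ParseError(
                    f"malformed intercepts header {text!r}", line=i)
            if not 0 <= n_intercepts <= 4:
                raise ParseError(
                    f"intercept count must be 0-4, got {n_intercepts}",
                    line=i)
            continue
        body.append((i, raw))
    pixels: List[PixelPoint] = []
    for i, raw in body:
        pixels.extend(parse_pixel_lines([raw], start_line=i))
    if n_intercepts is None:
        n_intercepts = min(4, len(pixels))
    if n_intercepts > len(pixels):
        raise ParseError(
            f"intercepts header claims {n_intercepts} pixels but file has "
            f"only {len(pixels)}")
    s.intercept_pixels = pixels[:n_intercepts]
    s.raw_points = pixels[n_intercepts:]
    return s
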