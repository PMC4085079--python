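"""Axis calibration and the pixel-to-data coordinate transform.

A figure's coordinate system is fixed by four clicked pixels: ``p1`` and
``p2`` on the y-axis, whose data values are ``y2`` and ``y1``, and ``p3``
and ``p4`` on the x-axis with values ``x1`` and ``x2``.  Two direction
vectors follow:

    a = p1 - p2     (along the y-axis, from value y1 towards y2)
    b = p4 - p3     (along the x-axis, from value x1 towards x2)

Any further pixel ``p5`` is decomposed over these vectors by intersecting
``p5`` with lines parallel to each axis, which yields dimensionless
coefficients

    ka = [(p51-p21)*b2 - (p52-p22)*b1] / (a1*b2 - a2*b1)
    kb = [(p51-p31)*a2 - (p52-p32)*a1] / (a2*b1 - a1*b2)

that measure the fractional position of ``p5`` along each calibrated span.
The data coordinates are then

    x = x1 + kb*(x2 - x1)
    y = y1 + ka*(y2 - y1)            (linear y-axis)
    y = y1 * (y2/y1)**ka             (logarithmic y-axis, y1, y2 > 0)

Because the decomposition uses the axis vectors themselves rather than the
image rows and columns, the transform is invariant under any invertible
affine map of the pixel plane: a rotated or linearly skewed figure (the
typical result of scanning or photocopying a printed page) digitizes to the
same data values as the undistorted original.  Nonlinear warp is outside
the model.

A solution exists iff ``a`` and ``b`` are linearly independent, i.e.
``a1*b2 != a2*b1``.  The resolution limit of clicking is summarized per
axis as the change in data units caused by selecting a neighbouring pixel:

    x_err = |x1 - x2| / ||b||
    y_err = |y1 - y2| / ||a||        (undefined for a logarithmic y-axis)

Pixel convention: image coordinates, origin at the top-left, ``col``
increasing rightward and ``row`` increasing downward, 0-based.  Clicks are
integer-valued but real-valued (sub-pixel) positions are accepted
throughout so that synthetic ground truths can be exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence, Union

from .errors import (
    CollinearAxesError,
    DegenerateSpanError,
    LogDomainError,
    ZeroLengthAxisError,
)

__all__ = [
    "PixelPoint",
    "AxisCalibration",
    "CoordinateSystem",
    "Coefficients",
    "DataPoint",
    "ClickError",
    "build_coordinate_system",
    "solve_coefficients",
    "pixel_to_data",
    "data_to_pixel",
    "clicking_error",
    "COLLINEARITY_RTOL",
]

#: Relative collinearity tolerance: axes are rejected when
#: |det| <= COLLINEARITY_RTOL * ||a|| * ||b||.  Scale-invariant, so the
#: same calibration passes or fails regardless of image resolution.
COLLINEARITY_RTOL = 1e-12

YScale = Literal["linear", "log"]


@dataclass(frozen=True)
class PixelPoint:
    """An image location: column (rightward) and row (downward)."""

    col: float
    row: float

    def __iter__(self):
        yield self.col
        yield self.row

    def __add__(self, other: "PixelPoint") -> "PixelPoint":
        return PixelPoint(self.col + other.col, self.row + other.row)

    def __sub__(self, other: "PixelPoint") -> "PixelPoint":
        return PixelPoint(self.col - other.col, self.row - other.row)


PixelLike = Union[PixelPoint, Sequence[float]]


def as_pixel(p: PixelLike) -> PixelPoint:
    """Coerce a ``(col, row)`` pair into a :class:`PixelPoint`."""
    if isinstance(p, PixelPoint):
        return p
    col, row = p
    return PixelPoint(float(col), float(row))


@dataclass(frozen=True)
class DataPoint:
    """A coordinate pair in axis units."""

    x: float
    y: float

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass(frozen=True)
class AxisCalibration:
    """The user-supplied frame: four intercept pixels and their values.

    ``p1``/``p2`` lie on the y-axis at values ``y2``/``y1``; ``p3``/``p4``
    lie on the x-axis at values ``x1``/``x2``.  (The seemingly reversed
    y-value order follows the natural clicking path from the top of the
    y-axis down to the origin and out along the x-axis.)  Sharing the
    origin pixel between the axes, ``p2 == p3``, is legal and common.
    """

    p1: PixelPoint
    p2: PixelPoint
    p3: PixelPoint
    p4: PixelPoint
    y2: float
    y1: float
    x1: float
    x2: float
    y_scale: YScale = "linear"


@dataclass(frozen=True)
class Coefficients:
    """Fractional positions of a pixel along the y- and x-axis spans.

    ``ka`` is 0 at value ``y1`` and 1 at ``y2``; ``kb`` is 0 at ``x1`` and
    1 at ``x2``.  Values outside [0, 1] are legal extrapolations.
    """

    ka: float
    kb: float


@dataclass(frozen=True)
class ClickError:
    """Data-unit change per pixel of click deviation, one value per axis.

    ``y_err`` is ``None`` for a logarithmic y-axis, where no single
    units-per-pixel figure exists.
    """

    x_err: float
    y_err: Optional[float]


@dataclass(frozen=True)
class CoordinateSystem:
    """A validated calibration; axis vectors are always re-derived.

    Construct via :func:`build_coordinate_system`, which enforces the
    invariants (non-zero axis vectors, non-degenerate spans, linear
    independence, positive log bounds).
    """

    calibration: AxisCalibration

    @property
    def a(self) -> PixelPoint:
        """y-axis vector p1 - p2."""
        return self.calibration.p1 - self.calibration.p2

    @property
    def b(self) -> PixelPoint:
        """x-axis vector p4 - p3."""
        return self.calibration.p4 - self.calibration.p3

    @property
    def det(self) -> float:
        """a1*b2 - a2*b1; non-zero iff the axes are linearly independent."""
        a, b = self.a, self.b
        return a.col * b.row - a.row * b.col


def build_coordinate_system(cal: AxisCalibration) -> CoordinateSystem:
    """Validate a calibration and wrap it as a :class:`CoordinateSystem`.

    Raises
    ------
    ZeroLengthAxisError
        if ``p1 == p2`` or ``p3 == p4``.
    DegenerateSpanError
        if ``y1 == y2`` or ``x1 == x2``.
    LogDomainError
        if ``y_scale == "log"`` with a non-positive ``y1`` or ``y2``.
    CollinearAxesError
        if ``|det| <= COLLINEARITY_RTOL * ||a|| * ||b||``.
    """
    a = cal.p1 - cal.p2
    b = cal.p4 - cal.p3
    norm_a = math.hypot(a.col, a.row)
    norm_b = math.hypot(b.col, b.row)
    if norm_a == 0.0 or norm_b == 0.0:
        raise ZeroLengthAxisError(
            "axis intercept pixels coincide: "
            f"{'p1 == p2' if norm_a == 0.0 else 'p3 == p4'}")
    if cal.y1 == cal.y2 or cal.x1 == cal.x2:
        raise DegenerateSpanError(
            "axis intercept values are equal: "
            f"{'y1 == y2' if cal.y1 == cal.y2 else 'x1 == x2'}")
    if cal.y_scale == "log" and (cal.y1 <= 0 or cal.y2 <= 0):
        raise LogDomainError(
            "logarithmic y-axis requires y1 > 0 and y2 > 0, got "
            f"y1={cal.y1}, y2={cal.y2}")
    det = a.col * b.row - a.row * b.col
    if abs(det) <= COLLINEARITY_RTOL * norm_a * norm_b:
        raise CollinearAxesError(
            f"axis vectors are collinear (|det|={abs(det):.3g}); "
            "no coordinate transform exists")
    return CoordinateSystem(cal)


def solve_coefficients(cs: CoordinateSystem, p5: PixelLike) -> Coefficients:
    """Decompose pixel ``p5`` over the axis vectors (closed form)."""
    p5 = as_pixel(p5)
    cal = cs.calibration
    a, b, det = cs.a, cs.b, cs.det
    ka = ((p5.col - cal.p2.col) * b.row - (p5.row - cal.p2.row) * b.col) / det
    kb = ((p5.col - cal.p3.col) * a.row - (p5.row - cal.p3.row) * a.col) / -det
    return Coefficients(ka, kb)


def pixel_to_data(cs: CoordinateSystem, p5: PixelLike) -> DataPoint:
    """Transform a clicked pixel into data coordinates.

    Extrapolation beyond the calibrated span is permitted and finite.
    """
    cal = cs.calibration
    k = solve_coefficients(cs, p5)
    x = cal.x1 + k.kb * (cal.x2 - cal.x1)
    if cal.y_scale == "log":
        y = cal.y1 * (cal.y2 / cal.y1) ** k.ka
    else:
        y = cal.y1 + k.ka * (cal.y2 - cal.y1)
    return DataPoint(x, y)


def data_to_pixel(cs: CoordinateSystem, d: DataPoint) -> PixelPoint:
    """Inverse transform: the unique pixel that maps to data point ``d``.

    Returns real-valued (sub-pixel) coordinates; callers needing screen
    pixels round explicitly.  Raises :class:`LogDomainError` for ``d.y <= 0``
    under a logarithmic y-axis.
    """
    cal = cs.calibration
    kb = (d.x - cal.x1) / (cal.x2 - cal.x1)
    if cal.y_scale == "log":
        if d.y <= 0:
            raise LogDomainError(
                f"cannot place y={d.y} on a logarithmic y-axis")
        ka = math.log(d.y / cal.y1) / math.log(cal.y2 / cal.y1)
    else:
        ka = (d.y - cal.y1) / (cal.y2 - cal.y1)
    # Invert the affine map p5 -> (ka, kb).  In matrix form
    #   [ b2 -b1] [p51]   [ka*det + b2*p21 - b1*p22]
    #   [-a2  a1] [p52] = [kb*det - a2*p31 + a1*p32]
    # whose coefficient matrix has determinant det, so the adjugate gives
    # the solution directly.
    a, b, det = cs.a, cs.b, cs.det
    r1 = ka * det + b.row * cal.p2.col - b.col * cal.p2.row
    r2 = kb * det - a.row * cal.p3.col + a.col * cal.p3.row
    col = (a.col * r1 + b.col * r2) / det
    row = (a.row * r1 + b.row * r2) / det
    return PixelPoint(col, row)


def clicking_error(cs: CoordinateSystem) -> ClickError:
    """Per-axis data-unit error caused by a one-pixel click deviation."""
    cal = cs.calibration
    a, b = cs.a, cs.b
    x_err = abs(cal.x1 - cal.x2) / math.hypot(b.col, b.row)
    if cal.y_scale == "log":
        y_err = None
    else:
        y_err = abs(cal.y1 - cal.y2) / math.hypot(a.col, a.row)
    return ClickError(x_err, y_err)
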