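"""Synthetic ground-truth figures and simulated click streams.

A fixture is a chart whose data points are known exactly: a calibration
frame in an undistorted pixel plane, a list of truth points in axis units,
and an affine distortion (2x2 matrix plus offset) applied to every pixel.
The built-in scenarios emulate a clean chart, the same chart rotated 18
degrees counter-clockwise, and the rotated chart additionally sheared
horizontally — the classic artefacts of scanning or photocopying a printed
page.  Because the distortion is affine, a correct digitizer must recover
the truth points exactly (up to click noise and pixel rounding) in every
scenario; the fixtures therefore double as an end-to-end accuracy
benchmark that needs no external data.

The default chart spans y: 0-9 over 300 px and x: 0-18 over 400 px with a
shared origin pixel, and carries ten integer-coordinate points starting at
(0, 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import SingularDistortionError
from .geometry import (
    AxisCalibration,
    DataPoint,
    PixelPoint,
    build_coordinate_system,
    data_to_pixel,
)
from .session import AxisValues, CaptureSession

__all__ = ["Fixture", "make_fixture", "simulate_clicks", "digitize",
           "render_figure", "DEFAULT_TRUTH_POINTS", "SCENARIOS"]

SCENARIOS = ("plain", "rotated", "rotated_skewed", "custom")

#: Default truth series: integer grid points x = 0..18 step 2, y in [0, 9],
#: beginning at (0, 3).
DEFAULT_TRUTH_POINTS: Tuple[DataPoint, ...] = tuple(
    DataPoint(x, y) for x, y in
    [(0, 3), (2, 5), (4, 6), (6, 7), (8, 8), (10, 8),
     (12, 7), (14, 6), (16, 5), (18, 4)])

_MARGIN = 60.0


def _default_calibration(y_scale: str = "linear") -> AxisCalibration:
    if y_scale == "log":
        return AxisCalibration(
            PixelPoint(100, 100), PixelPoint(100, 400),
            PixelPoint(100, 400), PixelPoint(500, 400),
            y2=100.0, y1=1.0, x1=0.0, x2=18.0, y_scale="log")
    return AxisCalibration(
        PixelPoint(100, 100), PixelPoint(100, 400),
        PixelPoint(100, 400), PixelPoint(500, 400),
        y2=9.0, y1=0.0, x1=0.0, x2=18.0, y_scale="linear")


@dataclass(frozen=True)
class Fixture:
    """A synthetic figure with known truth coordinates and distortion."""

    calibration: AxisCalibration
    matrix: Tuple[Tuple[float, float], Tuple[float, float]]
    offset: Tuple[float, float]
    truth_points: Tuple[DataPoint, ...]
    noise_px: float = 0.0
    seed: int = 0
    width: int = 600
    height: int = 500
    scenario: str = "custom"

    def distort(self, p: PixelPoint) -> PixelPoint:
        """Apply the affine distortion to an undistorted-frame pixel."""
        (m11, m12), (m21, m22) = self.matrix
        t1, t2 = self.offset
        return PixelPoint(m11 * p.col + m12 * p.row + t1,
                          m21 * p.col + m22 * p.row + t2)

    def truth_intercept_pixels(self) -> List[PixelPoint]:
        """Distorted positions of the four calibration pixels."""
        c = self.calibration
        return [self.distort(p) for p in (c.p1, c.p2, c.p3, c.p4)]

    def truth_data_pixels(self) -> List[PixelPoint]:
        """Exact (sub-pixel) distorted positions of the truth points."""
        cs = build_coordinate_system(self.calibration)
        return [self.distort(data_to_pixel(cs, d))
                for d in self.truth_points]

    def axis_values(self) -> AxisValues:
        c = self.calibration
        return AxisValues(c.y2, c.y1, c.x1, c.x2, c.y_scale)


def _rotation(angle_deg: float) -> np.ndarray:
    # In image coordinates (row increases downward) a visually
    # counter-clockwise rotation by theta maps (col, row) with
    # [[cos, sin], [-sin, cos]].
    t = math.radians(angle_deg)
    return np.array([[math.cos(t), math.sin(t)],
                     [-math.sin(t), math.cos(t)]])


def make_fixture(scenario: str = "plain", *,
                 angle_deg: float = 18.0,
                 shear: float = 0.2,
                 noise_px: float = 0.0,
                 seed: int = 0,
                 calibration: Optional[AxisCalibration] = None,
                 truth_points: Optional[Sequence[DataPoint]] = None,
                 matrix: Optional[Sequence[Sequence[float]]] = None,
                 y_scale: str = "linear") -> Fixture:
    """Build a fixture for one of the distortion scenarios.

    ``plain`` applies the identity; ``rotated`` an 18 degree
    counter-clockwise rotation; ``rotated_skewed`` the same rotation
    composed with a horizontal shear (factor 0.2 by default).  ``custom``
    takes an explicit 2x2 ``matrix``.  The translation part is always
    chosen so the distorted chart sits inside a positive canvas with a
    margin.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    cal = calibration if calibration is not None \
        else _default_calibration(y_scale)
    points = tuple(truth_points) if truth_points is not None \
        else (DEFAULT_TRUTH_POINTS if cal.y_scale == "linear"
              else tuple(DataPoint(x, 10 ** (y / 4.5))
                         for x, y in DEFAULT_TRUTH_POINTS))
    if scenario == "plain":
        m = np.eye(2)
    elif scenario == "rotated":
        m = _rotation(angle_deg)
    elif scenario == "rotated_skewed":
        m = np.array([[1.0, shear], [0.0, 1.0]]) @ _rotation(angle_deg)
    else:
        if matrix is None:
            raise ValueError("custom scenario requires an explicit matrix")
        m = np.asarray(matrix, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("distortion matrix must be 2x2")
    if abs(np.linalg.det(m)) <= 1e-9:
        raise SingularDistortionError(
            f"distortion matrix {m.tolist()} is singular")
    # Undistorted content bounding box: frame pixels plus a margin.
    frame = np.array([[0.0, 0.0], [600.0, 0.0], [0.0, 500.0], [600.0, 500.0]])
    mapped = frame @ m.T
    lo = mapped.min(axis=0)
    hi = mapped.max(axis=0)
    offset = (float(_MARGIN - lo[0]), float(_MARGIN - lo[1]))
    width = int(math.ceil(hi[0] - lo[0] + 2 * _MARGIN))
    height = int(math.ceil(hi[1] - lo[1] + 2 * _MARGIN))
    return Fixture(calibration=cal,
                   matrix=((float(m[0, 0]), float(m[0, 1])),
                           (float(m[1, 0]), float(m[1, 1]))),
                   offset=offset, truth_points=points,
                   noise_px=float(noise_px), seed=int(seed),
                   width=width, height=height, scenario=scenario)


def simulate_clicks(f: Fixture, *, round_to_int: bool = True
                    ) -> List[PixelPoint]:
    """Simulate a user digitizing the fixture.

    Returns the four intercept clicks followed by one click per truth
    point.  Each click is the exact distorted pixel plus an independent
    uniform offset in ``[-noise_px, +noise_px]`` per component (seeded by
    the fixture), then rounded to integer pixels; ``round_to_int=False``
    keeps the sub-pixel positions for zero-error round-trip checks.
    """
    exact = f.truth_intercept_pixels() + f.truth_data_pixels()
    coords = np.array([[p.col, p.row] for p in exact])
    if f.noise_px > 0:
        rng = np.random.default_rng(f.seed)
        coords = coords + rng.uniform(-f.noise_px, f.noise_px, coords.shape)
    if round_to_int:
        coords = np.rint(coords)
    return [PixelPoint(float(c), float(r)) for c, r in coords]


def digitize(f: Fixture, *, round_to_int: bool = True) -> List[DataPoint]:
    """Full simulated round trip: click the fixture, then transform back."""
    clicks = simulate_clicks(f, round_to_int=round_to_int)
    s = CaptureSession()
    v = f.axis_values()
    s.set_axis_values(v.y2, v.y1, v.x1, v.x2, v.y_scale)
    s.toggle_capturing()
    for p in clicks:
        s.add_pixel(p)
    return s.derive_output().points


def _axis_ticks(cal: AxisCalibration):
    """Integer-valued tick positions along each axis (undistorted frame)."""
    cs = build_coordinate_system(cal)
    ticks = []
    x_lo, x_hi = sorted((cal.x1, cal.x2))
    for xv in range(int(math.ceil(x_lo)), int(math.floor(x_hi)) + 1, 2):
        ticks.append(("x", xv, data_to_pixel(cs, DataPoint(xv, cal.y1))))
    if cal.y_scale == "linear":
        y_lo, y_hi = sorted((cal.y1, cal.y2))
        yv_range = range(int(math.ceil(y_lo)), int(math.floor(y_hi)) + 1)
    else:
        lo = int(math.ceil(math.log10(min(cal.y1, cal.y2))))
        hi = int(math.floor(math.log10(max(cal.y1, cal.y2))))
        yv_range = [10 ** k for k in range(lo, hi + 1)]
    for yv in yv_range:
        ticks.append(("y", yv, data_to_pixel(cs, DataPoint(cal.x1, yv))))
    return ticks


def render_figure(f: Fixture, path, sidecar_path=None):
    """Write the fixture as a PNG chart plus a truth sidecar text file.

    Axes, ticks and markers are drawn at their distorted positions (tick
    label glyphs themselves are not warped).  The sidecar uses the session
    file dialect: axis values header, then the four intercept pixels and
    the exact marker-centre pixels, so the render can be digitized and
    checked against truth without reading the image.  Returns
    ``(path, sidecar_path)``.
    """
    from PIL import Image, ImageDraw

    sidecar_path = sidecar_path if sidecar_path is not None \
        else str(path) + ".truth.txt"
    img = Image.new("RGB", (f.width, f.height), "white")
    draw = ImageDraw.Draw(img)
    cal = f.calibration
    p1, p2, p3, p4 = f.truth_intercept_pixels()

    def line(a: PixelPoint, b: PixelPoint, width=2):
        draw.line([(a.col, a.row), (b.col, b.row)], fill="black", width=width)

    line(p1, p2)
    line(p3, p4)
    # ticks: 6 px long in the undistorted frame, perpendicular to the axis
    for axis, value, base in _axis_ticks(cal):
        d = PixelPoint(0, 6) if axis == "x" else PixelPoint(-6, 0)
        a = f.distort(base)
        b = f.distort(base + d)
        line(a, b, width=1)
        lbl = f"{value:g}"
        anchor = f.distort(base + PixelPoint(0, 12) if axis == "x"
                           else base + PixelPoint(-24, -6))
        draw.text((anchor.col, anchor.row), lbl, fill="black")
    for p in f.truth_data_pixels():
        r = 4
        draw.ellipse([p.col - r, p.row - r, p.col + r, p.row + r],
                     outline="black", fill="gray")
    img.save(path, format="PNG")

    s = CaptureSession()
    v = f.axis_values()
    s.set_axis_values(v.y2, v.y1, v.x1, v.x2, v.y_scale)
    s.intercept_pixels = [p1, p2, p3, p4]
    s.raw_points = list(f.truth_data_pixels())
    with open(sidecar_path, "w") as fh:
        fh.write(f"# truth sidecar for synthetic fixture "
                 f"(scenario={f.scenario})\n")
        s.save(fh)
    return path, sidecar_path
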