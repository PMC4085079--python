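import numpy as np
import pytest

from figdig import (
    AxisCalibration,
    CalibrationError,
    PixelPoint,
    build_coordinate_system,
)

# Reference frame used throughout: y-axis 300 px tall (values 0..9),
# x-axis 400 px wide (values 0..18), shared origin pixel.
REF_FRAME = dict(
    p1=PixelPoint(100, 100), p2=PixelPoint(100, 400),
    p3=PixelPoint(100, 400), p4=PixelPoint(500, 400))
REF_VALUES = dict(y2=9.0, y1=0.0, x1=0.0, x2=18.0)


@pytest.fixture
def ref_calibration():
    return AxisCalibration(**REF_FRAME, **REF_VALUES)


@pytest.fixture
def ref_cs(ref_calibration):
    return build_coordinate_system(ref_calibration)


def random_coordinate_system(rng: np.random.Generator, y_scale="linear"):
    """A well-conditioned random calibration for property loops."""
    while True:
        pts = rng.uniform(-500.0, 500.0, (4, 2))
        if y_scale == "log":
            vals = rng.uniform(0.1, 100.0, 4)
        else:
            vals = rng.uniform(-50.0, 50.0, 4)
        if abs(vals[0] - vals[1]) < 0.5 or abs(vals[2] - vals[3]) < 0.5:
            continue
        cal = AxisCalibration(
            PixelPoint(*pts[0]), PixelPoint(*pts[1]),
            PixelPoint(*pts[2]), PixelPoint(*pts[3]),
            y2=vals[0], y1=vals[1], x1=vals[2], x2=vals[3],
            y_scale=y_scale)
        try:
            cs = build_coordinate_system(cal)
        except CalibrationError:
            continue
        a, b = cs.a, cs.b
        norm = np.hypot(*a) * np.hypot(*b)
        if abs(cs.det) > 0.05 * norm:  # keep the 2x2 system well conditioned
            return cs
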