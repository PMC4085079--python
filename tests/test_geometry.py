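"""Vector-calibration math: worked values, invariances, inverse map."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from figdig import (
    AxisCalibration,
    CollinearAxesError,
    DataPoint,
    DegenerateSpanError,
    LogDomainError,
    PixelPoint,
    ZeroLengthAxisError,
    build_coordinate_system,
    clicking_error,
    data_to_pixel,
    pixel_to_data,
    solve_coefficients,
)
from conftest import REF_FRAME, REF_VALUES, random_coordinate_system


def close(a, b, tol=1e-9):
    return math.isclose(a, b, rel_tol=tol, abs_tol=tol)


class TestBuildCoordinateSystem:
    def test_reference_frame_vectors(self, ref_cs):
        assert tuple(ref_cs.a) == (0, -300)
        assert tuple(ref_cs.b) == (400, 0)
        assert ref_cs.det == 120000

    def test_shared_origin_pixel_is_legal(self, ref_calibration):
        # p2 == p3 mimics clicking the origin once for both axes
        assert ref_calibration.p2 == ref_calibration.p3
        build_coordinate_system(ref_calibration)

    @pytest.mark.parametrize("cal, err", [
        (AxisCalibration(PixelPoint(0, 0), PixelPoint(1, 1),
                         PixelPoint(0, 0), PixelPoint(2, 2),
                         **REF_VALUES), CollinearAxesError),
        (AxisCalibration(PixelPoint(5, 5), PixelPoint(5, 5),
                         PixelPoint(0, 0), PixelPoint(2, 0),
                         **REF_VALUES), ZeroLengthAxisError),
        (AxisCalibration(**REF_FRAME, y2=9, y1=9, x1=0, x2=18),
         DegenerateSpanError),
        (AxisCalibration(**REF_FRAME, y2=9, y1=0, x1=3, x2=3),
         DegenerateSpanError),
        (AxisCalibration(**REF_FRAME, y2=9, y1=0, x1=0, x2=18,
                         y_scale="log"), LogDomainError),
        (AxisCalibration(**REF_FRAME, y2=-1, y1=2, x1=0, x2=18,
                         y_scale="log"), LogDomainError),
    ])
    def test_degenerate_calibrations_raise(self, cal, err):
        with pytest.raises(err):
            build_coordinate_system(cal)

    def test_solvability_dichotomy_near_collinear(self):
        # axes barely independent succeed; exactly collinear always fail
        cal = AxisCalibration(PixelPoint(0, 0), PixelPoint(100, 100),
                              PixelPoint(0, 0), PixelPoint(100, 100 + 1e-6),
                              **REF_VALUES)
        build_coordinate_system(cal)
        cal_exact = AxisCalibration(PixelPoint(0, 0), PixelPoint(100, 100),
                                    PixelPoint(0, 0), PixelPoint(200, 200),
                                    **REF_VALUES)
        with pytest.raises(CollinearAxesError):
            build_coordinate_system(cal_exact)


class TestSolveCoefficients:
    def test_midpoint_pixel(self, ref_cs):
        k = solve_coefficients(ref_cs, PixelPoint(300, 250))
        assert k.ka == 0.5 and k.kb == 0.5

    def test_coefficients_vanish_at_base_intercepts(self, ref_cs):
        cal = ref_cs.calibration
        assert solve_coefficients(ref_cs, cal.p2).ka == 0.0
        assert solve_coefficients(ref_cs, cal.p3).kb == 0.0

    @given(st.integers(-10000, 10000), st.integers(-10000, 10000))
    @settings(derandomize=True)
    def test_translation_invariance_exact(self, dc, dr):
        # integer-valued clicks, so the translation cancels exactly
        cs = build_coordinate_system(AxisCalibration(
            PixelPoint(103, 97), PixelPoint(141, 412),
            PixelPoint(141, 412), PixelPoint(522, 388), **REF_VALUES))
        p5 = PixelPoint(301, 247)
        shift = PixelPoint(dc, dr)
        cal = cs.calibration
        shifted = AxisCalibration(
            cal.p1 + shift, cal.p2 + shift, cal.p3 + shift, cal.p4 + shift,
            cal.y2, cal.y1, cal.x1, cal.x2, cal.y_scale)
        k0 = solve_coefficients(cs, p5)
        k1 = solve_coefficients(build_coordinate_system(shifted), p5 + shift)
        assert k0 == k1  # exact: integer shifts cancel in the differences

    def test_closed_form_equals_generic_linear_solve(self):
        # independent oracle: solve the two intersection systems
        #   ka*a + kbeta*b = p5 - p2,  kalpha*a + kb*b = p5 - p3
        # with a generic matrix method and compare ka, kb
        rng = np.random.default_rng(42)
        for _ in range(1000):
            cs = random_coordinate_system(rng)
            cal = cs.calibration
            p5 = PixelPoint(*rng.uniform(-600, 600, 2))
            M = np.array([[cs.a.col, cs.b.col], [cs.a.row, cs.b.row]])
            ka_ref = np.linalg.solve(
                M, [p5.col - cal.p2.col, p5.row - cal.p2.row])[0]
            kb_ref = np.linalg.solve(
                M, [p5.col - cal.p3.col, p5.row - cal.p3.row])[1]
            k = solve_coefficients(cs, p5)
            assert close(k.ka, ka_ref, 1e-12)
            assert close(k.kb, kb_ref, 1e-12)


class TestPixelToData:
    def test_sample_figure_midpoint(self, ref_cs):
        d = pixel_to_data(ref_cs, PixelPoint(300, 250))
        assert (d.x, d.y) == (9.0, 4.5)

    def test_log_scale_geometric_midpoint(self):
        cal = AxisCalibration(**REF_FRAME, y2=100, y1=1, x1=0, x2=18,
                              y_scale="log")
        cs = build_coordinate_system(cal)
        d = pixel_to_data(cs, PixelPoint(300, 250))
        assert close(d.y, 10.0, 1e-12)

    def test_shared_origin_maps_to_origin_values(self, ref_cs):
        d = pixel_to_data(ref_cs, ref_cs.calibration.p2)
        assert (d.x, d.y) == (0.0, 0.0)

    def test_log_equals_exponentiated_linear(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            cs_log = random_coordinate_system(rng, y_scale="log")
            cal = cs_log.calibration
            cs_lin = build_coordinate_system(AxisCalibration(
                cal.p1, cal.p2, cal.p3, cal.p4,
                math.log(cal.y2), math.log(cal.y1), cal.x1, cal.x2,
                "linear"))
            p5 = PixelPoint(*rng.uniform(-600, 600, 2))
            y_log = pixel_to_data(cs_log, p5).y
            y_lin = math.exp(pixel_to_data(cs_lin, p5).y)
            assert close(y_log, y_lin, 1e-12)

    @pytest.mark.parametrize("angle,shear", [
        (18.0, 0.0),   # rotation only
        (18.0, 0.2),   # rotation plus horizontal shear
        (-137.0, -0.6),
    ])
    def test_affine_invariance(self, ref_cs, angle, shear):
        # applying any invertible affine map to all five pixels leaves the
        # recovered data coordinates unchanged
        t = math.radians(angle)
        M = np.array([[1.0, shear], [0.0, 1.0]]) @ np.array(
            [[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])
        off = np.array([37.0, -81.0])

        def T(p):
            v = M @ [p.col, p.row] + off
            return PixelPoint(*v)

        cal = ref_cs.calibration
        warped = build_coordinate_system(AxisCalibration(
            T(cal.p1), T(cal.p2), T(cal.p3), T(cal.p4), **REF_VALUES))
        rng = np.random.default_rng(11)
        for _ in range(200):
            p5 = PixelPoint(*rng.uniform(0, 600, 2))
            d0 = pixel_to_data(ref_cs, p5)
            d1 = pixel_to_data(warped, T(p5))
            assert close(d0.x, d1.x) and close(d0.y, d1.y)


class TestDataToPixel:
    def test_inverse_of_worked_example(self, ref_cs):
        p = data_to_pixel(ref_cs, DataPoint(9, 4.5))
        assert close(p.col, 300) and close(p.row, 250)

    def test_origin_round_trip(self, ref_cs):
        p = data_to_pixel(ref_cs, DataPoint(0, 0))
        assert close(p.col, 100) and close(p.row, 400)

    def test_log_domain_rejected(self):
        cal = AxisCalibration(**REF_FRAME, y2=100, y1=1, x1=0, x2=18,
                              y_scale="log")
        cs = build_coordinate_system(cal)
        with pytest.raises(LogDomainError):
            data_to_pixel(cs, DataPoint(3, 0.0))

    @pytest.mark.parametrize("y_scale", ["linear", "log"])
    def test_round_trip_identity(self, y_scale):
        rng = np.random.default_rng(5)
        worst = 0.0
        for _ in range(1000):
            cs = random_coordinate_system(rng, y_scale=y_scale)
            cal = cs.calibration
            x = rng.uniform(*sorted((cal.x1, cal.x2)))
            y = rng.uniform(*sorted((cal.y1, cal.y2)))
            d = DataPoint(x, y)
            back = pixel_to_data(cs, data_to_pixel(cs, d))
            worst = max(worst, abs(back.x - d.x), abs(back.y - d.y))
        assert worst < 1e-9


class TestClickingError:
    def test_reference_values(self, ref_cs):
        err = clicking_error(ref_cs)
        assert err.x_err == 18 / 400 == 0.045
        assert err.y_err == 9 / 300 == 0.03

    def test_log_scale_has_no_y_error(self):
        cal = AxisCalibration(**REF_FRAME, y2=100, y1=1, x1=0, x2=18,
                              y_scale="log")
        err = clicking_error(build_coordinate_system(cal))
        assert err.y_err is None
        assert err.x_err == 0.045

    def test_errors_halve_with_doubled_pixel_spans(self, ref_cs):
        doubled = build_coordinate_system(AxisCalibration(
            PixelPoint(100, 100), PixelPoint(100, 700),
            PixelPoint(100, 700), PixelPoint(900, 700), **REF_VALUES))
        e0, e1 = clicking_error(ref_cs), clicking_error(doubled)
        assert close(e1.x_err, e0.x_err / 2)
        assert close(e1.y_err, e0.y_err / 2)

    def test_integer_rounding_error_within_bound(self, ref_cs):
        # quantizing exact pixels to the integer grid moves coordinates by
        # far less than twice the combined per-pixel click error
        err = clicking_error(ref_cs)
        bound = 2 * (err.x_err + err.y_err)
        rng = np.random.default_rng(17)
        worst = 0.0
        for _ in range(1000):
            d = DataPoint(rng.uniform(0, 18), rng.uniform(0, 9))
            p = data_to_pixel(ref_cs, d)
            back = pixel_to_data(
                ref_cs, PixelPoint(round(p.col), round(p.row)))
            worst = max(worst, abs(back.x - d.x), abs(back.y - d.y))
        assert worst <= bound
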