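"""Calibration fitting, evaluation, monotonicity and inversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermocr.calibration import (
    CalibrationPoint,
    CrCalibration,
    error_table,
    fit_curve,
    invert,
    max_abs_error,
    monotone_on,
    read_points_csv,
    reference_curve,
    write_points_csv,
)

REF_COEFFS = np.array([-11.0, 3.16e-1, -7.11e-3, 5.43e-5])


def _points_on(curve, temps):
    return [
        CalibrationPoint(temperature=t, mean_cr=curve.evaluate(t)[0], n_pixels=100)
        for t in temps
    ]


class TestFit:
    def test_noiseless_refit_recovers_coefficients(self, curve):
        points = _points_on(curve, np.arange(40.0, 101.0, 5.0))
        fitted = fit_curve(points, degree=3)
        assert fitted.coefficients_ == pytest.approx(REF_COEFFS, rel=1e-8)
        assert fitted.t_min_ == 40.0 and fitted.t_max_ == 100.0
        assert fitted.monotone_
        assert np.max(np.abs(fitted.residuals_)) < 1e-10

    def test_collinear_points_degree_one(self):
        t = np.array([10.0, 20.0, 30.0, 55.0])
        fitted = CrCalibration(degree=1).fit(t, 2.0 * t - 7.0)
        assert fitted.coefficients_ == pytest.approx([-7.0, 2.0], abs=1e-10)

    def test_underdetermined_fit_raises(self):
        points = _points_on(reference_curve(), [40.0, 60.0, 80.0])
        with pytest.raises(ValueError, match="distinct temperatures"):
            fit_curve(points, degree=3)

    def test_duplicate_temperatures_do_not_count(self):
        points = _points_on(reference_curve(), [40.0, 40.0, 40.0, 40.0, 60.0])
        with pytest.raises(ValueError):
            fit_curve(points, degree=3)

    def test_sklearn_param_surface(self):
        est = CrCalibration(degree=2)
        assert est.get_params() == {"degree": 2}
        est.set_params(degree=3)
        assert est.degree == 3


class TestEvaluate:
    @pytest.mark.parametrize(
        "t, expected",
        [(80.0, -3.4224), (100.0, 3.8), (40.0, -6.2608)],
    )
    def test_known_values(self, curve, t, expected):
        cr, out = curve.evaluate(t)
        assert cr == pytest.approx(expected, abs=1e-10)
        assert not out

    def test_out_of_range_flagged_not_raised(self, curve):
        _, out = curve.evaluate(25.0)
        assert out
        _, out = curve.evaluate(120.0)
        assert out


class TestMonotone:
    def test_reference_curve_increasing_on_range(self, curve):
        assert monotone_on(curve, 40.0, 100.0)

    def test_parabola_with_interior_vertex(self):
        c = CrCalibration.from_coefficients([0.0, -100.0, 1.0, 0.0], 0.0, 100.0)
        assert not c.monotone_on(0.0, 100.0)
        assert not c.monotone_

    def test_constant_curve_not_monotone(self):
        c = CrCalibration.from_coefficients([5.0, 0.0, 0.0, 0.0], 0.0, 10.0)
        assert not c.monotone_

    def test_agrees_with_dense_sampling(self, rng):
        for _ in range(50):
            coeffs = rng.normal(scale=[5.0, 0.5, 5e-3, 5e-5])
            c = CrCalibration.from_coefficients(coeffs, 40.0, 100.0)
            t = np.linspace(40.0, 100.0, 5001)
            d = np.diff(c.predict(t))
            d = d[np.abs(d) > 1e-12]
            sampled = d.size > 0 and (np.all(d > 0) or np.all(d < 0))
            assert c.monotone_on(40.0, 100.0) == sampled


class TestInvert:
    def test_known_inverse(self, curve):
        t, status = invert(curve, -3.4224)
        assert t == pytest.approx(80.0, abs=1e-4)
        assert status == "in_range"

    def test_clamping_below_and_above(self, curve):
        assert invert(curve, -100.0) == (40.0, "clamped_low")
        assert invert(curve, 50.0) == (100.0, "clamped_high")

    def test_round_trip_on_half_degree_grid(self, curve):
        for t in np.arange(40.0, 100.001, 0.5):
            cr, _ = curve.evaluate(t)
            t_back, status = curve.invert(cr)
            assert status == "in_range" or t in (40.0, 100.0)
            assert t_back == pytest.approx(t, abs=1e-4)

    @given(st.floats(min_value=-6.2608, max_value=3.8))
    def test_evaluate_of_invert_is_identity(self, cr):
        curve = reference_curve()
        t, _ = curve.invert(cr)
        back, _ = curve.evaluate(t)
        assert abs(back - cr) <= 1e-6 * max(1.0, abs(cr))

    @given(
        st.floats(min_value=-6.3, max_value=3.9),
        st.floats(min_value=-6.3, max_value=3.9),
    )
    def test_inverse_is_monotone_in_cr(self, cr1, cr2):
        curve = reference_curve()
        if cr1 > cr2:
            cr1, cr2 = cr2, cr1
        assert curve.invert(cr1)[0] <= curve.invert(cr2)[0] + 1e-9

    def test_array_inversion_matches_scalar(self, curve, rng):
        cr = rng.uniform(-8.0, 5.0, size=200)
        t_arr, status = curve.invert_array(cr)
        for i in range(cr.size):
            t_s, s_s = curve.invert(cr[i])
            assert t_arr[i] == pytest.approx(t_s, abs=1e-6)
            assert {"in_range": 0, "clamped_low": 1, "clamped_high": 2}[s_s] == status[i]

    def test_non_monotone_curve_refuses_inversion(self):
        c = CrCalibration.from_coefficients([0.0, -100.0, 1.0, 0.0], 0.0, 100.0)
        with pytest.raises(ValueError, match="monotone"):
            c.invert(5.0)

    def test_decreasing_curve_inverts_with_flipped_clamps(self):
        c = CrCalibration.from_coefficients([10.0, -0.5], 0.0, 10.0)
        t, status = c.invert(7.5)
        assert t == pytest.approx(5.0, abs=1e-6)
        assert status == "in_range"
        assert c.invert(100.0) == (0.0, "clamped_low")
        assert c.invert(-100.0) == (10.0, "clamped_high")


class TestErrorTable:
    def test_noiseless_points_give_zero_error(self, curve):
        points = _points_on(curve, np.arange(40.0, 101.0, 5.0))
        table = error_table(curve, points)
        assert len(table) == 13
        assert max_abs_error(table) < 1e-4
        assert np.allclose(
            table["error_C"],
            table["estimated_temperature_C"] - table["true_temperature_C"],
        )

    def test_error_grows_with_cr_offset(self, curve):
        base = curve.evaluate(60.0)[0]
        errors = []
        for delta in (0.01, 0.05, 0.2):
            pt = CalibrationPoint(temperature=60.0, mean_cr=base + delta)
            errors.append(error_table(curve, [pt])["error_C"].iloc[0])
        assert all(e > 0 for e in errors)
        assert errors == sorted(errors)

    def test_empty_points_give_empty_table(self, curve):
        table = error_table(curve, [])
        assert table.empty
        assert np.isnan(max_abs_error(table))


class TestSerialization:
    def test_json_round_trip(self, curve, tmp_path):
        path = tmp_path / "cal.json"
        curve.save(path, provenance={"inputs": "unit-test"})
        loaded = CrCalibration.load(path)
        assert np.allclose(loaded.coefficients_, curve.coefficients_)
        assert loaded.t_min_ == curve.t_min_ and loaded.t_max_ == curve.t_max_
        assert loaded.monotone_

    def test_points_csv_round_trip(self, tmp_path):
        points = [
            CalibrationPoint(40.0, -6.2608, 0.9, 345600),
            CalibrationPoint(80.0, -3.4224, 1.1, 345600),
        ]
        path = tmp_path / "points.csv"
        write_points_csv(points, path)
        assert path.read_text().splitlines()[0] == "temperature_C,mean_cr,sd_cr,n_pixels"
        assert read_points_csv(path) == points

    def test_invalid_point_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPoint(temperature=float("nan"), mean_cr=0.0)
        with pytest.raises(ValueError):
            CalibrationPoint(temperature=40.0, mean_cr=0.0, n_pixels=0)
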