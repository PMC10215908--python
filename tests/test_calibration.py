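import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import fluoarea as fa
from fluoarea.calibration import (
    CalibrationPoint,
    CalibrationSet,
    DistanceCurve,
    area_from_lambda,
    fit_distance_curve,
    fit_lambda,
    interpolate_area,
    load_calibration_table,
    predict_area,
)
from fluoarea.errors import CalibrationRangeError, FitError, TableParseError

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False, allow_infinity=False)


class TestLambda:
    def test_coin_reference(self):
        # 380 / (33.4 * 0.002605) computed independently = 4367.464686...
        cal = fit_lambda(380.0, 33.4, 0.002605)
        assert cal.lam == pytest.approx(380.0 / (33.4 * 0.002605), rel=1e-15)
        assert cal.lam == pytest.approx(4367.4647, abs=5e-5)

    def test_identity(self):
        assert fit_lambda(1.0, 1.0, 1.0).lam == 1.0

    def test_linearity_in_ref_area(self):
        base = fit_lambda(200.0, 40.0, 0.01).lam
        assert fit_lambda(400.0, 40.0, 0.01).lam == pytest.approx(2 * base)

    @pytest.mark.parametrize("bad", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-5, 1, 1)])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError, match="positive"):
            fit_lambda(*bad)

    def test_worked_example_area(self):
        cal = fa.LambdaCalibration(lam=4376.0, ref_area=380.0,
                                   ref_distance=33.4, ref_ratio=0.002605)
        m = area_from_lambda(cal, 33.4, 0.008918)
        assert round(m.estimated_area, 2) == 1303.44
        assert m.method == "lambda"

    def test_zero_ratio_gives_zero_area(self):
        cal = fit_lambda(380.0, 33.4, 0.002605)
        assert area_from_lambda(cal, 50.0, 0.0).estimated_area == 0.0

    def test_reference_roundtrip(self):
        cal = fit_lambda(380.0, 33.4, 0.002605)
        m = area_from_lambda(cal, 33.4, 0.002605)
        assert m.estimated_area == pytest.approx(380.0, rel=1e-12)

    @pytest.mark.parametrize("ratio", [-0.1, 1.5])
    def test_bad_ratio_rejected(self, ratio):
        cal = fit_lambda(1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            area_from_lambda(cal, 1.0, ratio)

    @settings(max_examples=50, deadline=None)
    @given(positive, positive, st.floats(min_value=1e-6, max_value=1.0))
    def test_roundtrip_property(self, area, d, ratio):
        m = area_from_lambda(fit_lambda(area, d, ratio), d, ratio)
        assert m.estimated_area == pytest.approx(area, rel=1e-12)


class TestDistanceCurveFit:
    @pytest.mark.parametrize("distance,a1,a0,r2,a1_places", [
        (50.0, 0.0285, -18.7376, 0.9951, 4),
        (75.0, 0.0725, 18.6109, 0.9981, 4),
        (100.0, 0.136, -18.1121, 0.9953, 3),
    ])
    def test_reproduces_printed_coefficients(self, table1, distance, a1, a0, r2, a1_places):
        points = dict(table1)[distance]
        curve = fit_distance_curve(points, distance)
        assert round(curve.a1, a1_places) == a1
        assert round(curve.a0, 4) == a0
        assert round(curve.r2, 4) == r2
        assert curve.n == 8

    def test_exact_line(self):
        pts = [CalibrationPoint(area=p / 100.0, pixels=p) for p in (0.001, 100, 200)]
        curve = fit_distance_curve(pts, 60.0)
        assert curve.a0 == pytest.approx(0.0, abs=1e-12)
        assert curve.a1 == pytest.approx(0.01, rel=1e-12)
        assert curve.r2 == pytest.approx(1.0)

    def test_matches_scipy_linregress(self, table1):
        for distance, points in table1:
            x = [p.pixels for p in points]
            y = [p.area for p in points]
            ref = stats.linregress(x, y)
            curve = fit_distance_curve(points, distance)
            assert curve.a1 == pytest.approx(ref.slope, rel=1e-12)
            assert curve.a0 == pytest.approx(ref.intercept, rel=1e-10)
            assert curve.r2 == pytest.approx(ref.rvalue**2, rel=1e-10)

    def test_too_few_points(self):
        with pytest.raises(FitError, match=">= 2"):
            fit_distance_curve([CalibrationPoint(1.0, 1.0)], 50.0)

    def test_zero_pixel_variance(self):
        pts = [CalibrationPoint(1.0, 5.0), CalibrationPoint(2.0, 5.0)]
        with pytest.raises(FitError, match="variance"):
            fit_distance_curve(pts, 50.0)

    def test_residual_orthogonality(self, table1):
        for distance, points in table1:
            curve = fit_distance_curve(points, distance)
            x = np.array([p.pixels for p in points])
            y = np.array([p.area for p in points])
            resid = y - (curve.a0 + curve.a1 * x)
            scale = float(np.abs(y).sum())
            assert abs(resid.sum()) < 1e-8 * scale
            assert abs((resid * x).sum()) < 1e-8 * scale * float(np.abs(x).max())

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(1, 1e4), st.floats(1, 1e6)),
                    min_size=3, max_size=10, unique_by=lambda t: t[1]))
    def test_r2_bounds(self, raw):
        pts = [CalibrationPoint(area=a, pixels=p) for a, p in raw]
        curve = fit_distance_curve(pts, 50.0)
        assert -1e-12 <= curve.r2 <= 1.0 + 1e-12

    def test_scale_equivariance(self, table1):
        distance, points = table1[0]
        base = fit_distance_curve(points, distance)
        c = 3.5
        scaled_pts = [CalibrationPoint(area=p.area, pixels=p.pixels * c) for p in points]
        scaled = fit_distance_curve(scaled_pts, distance)
        assert scaled.a1 == pytest.approx(base.a1 / c, rel=1e-12)
        assert predict_area(scaled, 1000 * c) == pytest.approx(
            predict_area(base, 1000), rel=1e-12)


class TestPredict:
    def test_printed_50cm_curve_at_table_max(self, printed_curves):
        # -18.7376 + 0.0285 * 57437, hand arithmetic; true area was 1600
        area = predict_area(printed_curves.curves[0], 57437)
        assert area == pytest.approx(1618.2169, abs=1e-4)

    def test_identity_curve(self):
        c = DistanceCurve(50.0, a0=0.0, a1=1.0, r2=1.0, n=2)
        assert predict_area(c, 5) == 5.0

    def test_zero_pixels_gives_intercept(self, printed_curves):
        c = printed_curves.curves[0]
        assert predict_area(c, 0) == c.a0

    def test_negative_prediction_flagged(self, printed_curves):
        cal = CalibrationSet(curves=(printed_curves.curves[0],))
        m = interpolate_area(cal, 50.0, 0)
        assert m.estimated_area < 0
        assert any("negative" in w for w in m.warnings)


class TestInterpolation:
    def test_endpoint_identity(self, table1_calibration):
        cal = table1_calibration
        m = interpolate_area(cal, 50.0, 20000)
        assert m.method == "curve"
        assert m.estimated_area == predict_area(cal.curves[0], 20000)

    def test_midpoint_is_mean(self, table1_calibration):
        cal = table1_calibration
        f50 = predict_area(cal.curves[0], 10000)
        f75 = predict_area(cal.curves[1], 10000)
        m = interpolate_area(cal, 62.5, 10000)
        assert m.estimated_area == pytest.approx((f50 + f75) / 2, rel=1e-12)
        assert m.method == "interpolated"

    def test_printed_coefficients_worked_blend(self, printed_curves):
        # f50(30000)=836.2624, f75(30000)=2193.6109, blend factor 0.5/25=0.02
        m = interpolate_area(printed_curves, 50.5, 30000)
        assert round(m.estimated_area, 2) == 863.41

    def test_continuity_in_distance(self, table1_calibration):
        cal = table1_calibration
        eps = 1e-9
        for d in (50.0, 75.0, 100.0):
            at = interpolate_area(cal, d, 8000, allow_extrapolation=True).estimated_area
            below = interpolate_area(cal, max(d - eps, 50.0), 8000).estimated_area
            above = interpolate_area(cal, min(d + eps, 100.0), 8000).estimated_area
            assert at == pytest.approx(below, abs=1e-5)
            assert at == pytest.approx(above, abs=1e-5)

    def test_out_of_range_rejected(self, table1_calibration):
        with pytest.raises(CalibrationRangeError, match="outside"):
            interpolate_area(table1_calibration, 49.0, 10000)
        with pytest.raises(CalibrationRangeError, match="outside"):
            interpolate_area(table1_calibration, 101.0, 10000)

    def test_extrapolation_override(self, table1_calibration):
        m = interpolate_area(table1_calibration, 49.0, 10000, allow_extrapolation=True)
        assert any("extrapolating" in w for w in m.warnings)
        # linear extension of the 50/75 pair
        f50 = predict_area(table1_calibration.curves[0], 10000)
        f75 = predict_area(table1_calibration.curves[1], 10000)
        assert m.estimated_area == pytest.approx(f50 - (f75 - f50) / 25.0, rel=1e-10)

    def test_single_curve_set(self, printed_curves):
        cal = CalibrationSet(curves=(printed_curves.curves[0],))
        assert interpolate_area(cal, 50.0, 10000).method == "curve"
        with pytest.raises(CalibrationRangeError):
            interpolate_area(cal, 60.0, 10000)


class TestTableLoader:
    def test_shipped_table1(self, table1):
        assert [d for d, _ in table1] == [50.0, 75.0, 100.0]
        assert all(len(pts) == 8 for _, pts in table1)
        # thousands separators as printed are tolerated
        fifty = dict(table1)[50.0]
        assert any(p.pixels == 57437 for p in fifty)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("")
        with pytest.raises(TableParseError, match="empty"):
            load_calibration_table(p)

    def test_header_only(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("distance_cm,area_mm2,pixels\n")
        with pytest.raises(TableParseError, match="no data"):
            load_calibration_table(p)

    def test_bad_row_reports_row_number(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("distance_cm,area_mm2,pixels\n50,100,2127\n50,oops,33\n")
        with pytest.raises(TableParseError, match="row 3"):
            load_calibration_table(p)

    def test_nonpositive_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("distance_cm,area_mm2,pixels\n50,-1,2127\n")
        with pytest.raises(TableParseError, match="positive"):
            load_calibration_table(p)

    def test_duplicate_distance_blocks_merged(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("distance_cm,area_mm2,pixels\n"
                     "50,100,400\n75,100,200\n50,200,800\n")
        table = load_calibration_table(p)
        assert [d for d, _ in table] == [50.0, 75.0]
        assert len(dict(table)[50.0]) == 2


class TestPersistence:
    def test_json_roundtrip(self, tmp_path, table1):
        cal = fa.fit_calibration_set(table1, total_pixels=12_000_000)
        p = tmp_path / "cal.json"
        cal.to_json(p)
        back = CalibrationSet.from_json(p)
        assert back == cal
        payload = json.loads(p.read_text())
        assert payload["total_pixels"] == 12_000_000
        assert [c["distance_cm"] for c in payload["curves"]] == [50.0, 75.0, 100.0]

    def test_unsorted_curves_rejected(self):
        c1 = DistanceCurve(75.0, 0.0, 1.0, 1.0, 2)
        c2 = DistanceCurve(50.0, 0.0, 1.0, 1.0, 2)
        with pytest.raises(ValueError, match="increasing"):
            CalibrationSet(curves=(c1, c2))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            CalibrationSet(curves=())


def test_lambda_path_and_curve_path_agree_on_calibration_data(table1, table1_calibration):
    """Sanity link between the two calibration routes at a calibrated point."""
    total_pixels = 12_000_000
    pts = dict(table1)[50.0]
    biggest = max(pts, key=lambda p: p.pixels)
    lam = fit_lambda(biggest.area, 50.0, biggest.pixels / total_pixels)
    m_lambda = area_from_lambda(lam, 50.0, biggest.pixels / total_pixels)
    m_curve = interpolate_area(table1_calibration, 50.0, biggest.pixels)
    assert m_lambda.estimated_area == pytest.approx(biggest.area, rel=1e-12)
    assert m_curve.estimated_area == pytest.approx(biggest.area, rel=0.05)
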