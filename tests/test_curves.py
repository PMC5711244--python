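"""Hermite curve fitting: basis, allocation, subsampling, evaluation, revision."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contourfit.curves import (
    Contour,
    ControlPointSet,
    CurveSamplingParams,
    allocate_control_points,
    estimate_tangents,
    evaluate_curve,
    hermite_basis,
    load_contour,
    move_control_point,
    save_contour,
    subsample_control_points,
)

from conftest import circle_contour


class TestHermiteBasis:
    @pytest.mark.parametrize(
        "s, expected",
        [
            (0.0, (1.0, 0.0, 0.0, 0.0)),
            (1.0, (0.0, 1.0, 0.0, 0.0)),
            (0.5, (0.5, 0.5, 0.125, -0.125)),
        ],
    )
    def test_known_values(self, s, expected):
        assert hermite_basis(s) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize("s", [-0.1, 1.1, 2.0])
    def test_out_of_range_rejected(self, s):
        with pytest.raises(ValueError):
            hermite_basis(s)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=1000, derandomize=True)
    def test_positional_partition_of_unity(self, s):
        h1, h2, h3, h4 = hermite_basis(s)
        assert h1 + h2 == pytest.approx(1.0, abs=1e-12)

    def test_tangent_weights_vanish_at_endpoints(self):
        for s in (0.0, 1.0):
            _, _, h3, h4 = hermite_basis(s)
            assert h3 == 0.0 and h4 == 0.0


class TestAllocation:
    @pytest.mark.parametrize("length, expected", [(25, 6), (80, 10), (170, 20), (500, 30)])
    def test_band_values(self, length, expected):
        assert allocate_control_points(length) == expected

    def test_step_function_bounded_and_monotone(self):
        lengths = np.linspace(0.5, 2000.0, 4001)
        counts = np.array([allocate_control_points(l) for l in lengths])
        assert set(counts) == {6, 10, 20, 30}
        assert (counts <= 30).all()
        assert (np.diff(counts) >= 0).all()

    @pytest.mark.parametrize("length", [0.0, -5.0])
    def test_nonpositive_length_rejected(self, length):
        with pytest.raises(ValueError):
            allocate_control_points(length)


class TestTangents:
    def test_collinear_centered_difference(self):
        pts = [(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)]
        tan = estimate_tangents(pts, closed=True)
        np.testing.assert_allclose(tan[1], (1.0, 0.0))

    def test_regular_polygon_tangents_perpendicular_to_radius(self):
        poly = circle_contour(radius=10.0, n=12)
        tan = estimate_tangents(poly.points, closed=True)
        radial = poly.points - np.array([128.0, 128.0])
        dots = np.einsum("nd,nd->n", tan, radial)
        np.testing.assert_allclose(dots, 0.0, atol=1e-10)

    def test_matches_independent_centered_difference_loop(self, rng):
        pts = rng.normal(size=(17, 2)) * 10
        tan = estimate_tangents(pts, closed=True)
        for i in range(len(pts)):
            expected = (pts[(i + 1) % len(pts)] - pts[(i - 1) % len(pts)]) / 2.0
            np.testing.assert_array_equal(tan[i], expected)


class TestSubsampling:
    def test_square_equal_arc_spacing(self):
        square = Contour([(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)])
        assert square.length == pytest.approx(40.0)
        cps = subsample_control_points(square, 4)
        np.testing.assert_allclose(
            cps.points, [(0, 0), (10, 0), (10, 10), (0, 10)], atol=1e-12
        )

    def test_circle_spacing_uniform_within_segment_length(self):
        circle = circle_contour(radius=50.0, n=500)
        cps = subsample_control_points(circle, 20)
        arcs = np.hypot(*(np.roll(cps.points, -1, axis=0) - cps.points).T)
        seg_len = circle.segment_lengths.max()
        assert arcs.max() - arcs.min() < seg_len

    def test_allocated_count_never_exceeds_cap(self):
        for radius in (4.0, 20.0, 85.0, 300.0):
            circle = circle_contour(center=(0, 0), radius=radius, n=400)
            count = allocate_control_points(circle.length)
            cps = subsample_control_points(circle, count)
            assert 3 <= len(cps) <= 30

    def test_unresolvable_count_rejected(self):
        tiny = Contour([(0, 0), (1e-10, 0), (1e-10, 1e-10), (0, 1e-10)])
        with pytest.raises(ValueError):
            subsample_control_points(tiny, 30)


class TestEvaluateCurve:
    @pytest.mark.parametrize("count", [4, 10, 30])
    @pytest.mark.parametrize("delta_s", [0.1, 0.25, 0.5])
    def test_sample_count_grid(self, count, delta_s):
        cps = subsample_control_points(circle_contour(n=300), count)
        curve = evaluate_curve(cps, CurveSamplingParams(delta_s=delta_s))
        assert len(curve) == count * round(1 / delta_s)

    def test_interpolates_control_points_exactly(self):
        cps = subsample_control_points(circle_contour(n=300), 20)
        curve = evaluate_curve(cps, CurveSamplingParams(0.1))
        starts = curve.points[::10]  # s=0 sample of each segment
        np.testing.assert_array_equal(starts, cps.points)

    def test_collinear_control_points_stay_on_line(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6)])
        cps = ControlPointSet(pts, estimate_tangents(pts, closed=True))
        curve = evaluate_curve(cps, CurveSamplingParams(0.1))
        # tangents of a closed collinear loop are collinear with the line
        assert np.abs(curve.points[:, 1]).max() < 1e-12

    def test_matches_scalar_hand_expansion(self, rng):
        pts = rng.normal(size=(5, 2)) * 20
        cps = ControlPointSet(pts, estimate_tangents(pts, closed=True))
        curve = evaluate_curve(cps, CurveSamplingParams(0.1)).points
        seg = 2
        p0, p1 = cps.points[seg], cps.points[(seg + 1) % 5]
        u0, u1 = cps.tangents[seg], cps.tangents[(seg + 1) % 5]
        for s, idx in [(0.0, seg * 10), (0.5, seg * 10 + 5), (1.0, ((seg + 1) * 10) % 50)]:
            h1, h2, h3, h4 = hermite_basis(s)
            expected = h1 * p0 + h2 * p1 + h3 * u0 + h4 * u1
            np.testing.assert_allclose(curve[idx], expected, atol=1e-12)

    def test_invalid_delta_s_rejected(self):
        for bad in (0.0, 0.3, 0.6, -0.1):
            with pytest.raises(ValueError):
                CurveSamplingParams(delta_s=bad)


class TestMoveControlPoint:
    def test_noop_move_keeps_curve_identical(self):
        cps = subsample_control_points(circle_contour(n=300), 12)
        moved = move_control_point(cps, 5, cps.points[5])
        np.testing.assert_array_equal(
            evaluate_curve(moved).points, evaluate_curve(cps).points
        )

    def test_local_control_leaves_far_segments_bitwise_unchanged(self):
        cps = subsample_control_points(circle_contour(n=400), 20)
        before = evaluate_curve(cps).points.reshape(20, 10, 2)
        moved = move_control_point(cps, 7, cps.points[7] + (0.0, 3.0))
        after = evaluate_curve(moved).points.reshape(20, 10, 2)
        affected = {(7 + k) % 20 for k in (-2, -1, 0, 1)}
        unaffected = [i for i in range(20) if i not in affected]
        assert len(unaffected) >= 14
        for i in unaffected:
            np.testing.assert_array_equal(before[i], after[i])
        assert any(not np.array_equal(before[i], after[i]) for i in affected)

    def test_affected_segments_match_from_scratch_refit(self):
        square = Contour([(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)])
        cps = subsample_control_points(square, 4)
        moved = move_control_point(cps, 1, cps.points[1] + (0.0, 1.0))
        pts = cps.points.copy()
        pts[1] += (0.0, 1.0)
        scratch = ControlPointSet(pts, estimate_tangents(pts, closed=True))
        np.testing.assert_array_equal(
            evaluate_curve(moved).points, evaluate_curve(scratch).points
        )

    def test_index_out_of_range(self):
        cps = subsample_control_points(circle_contour(n=100), 6)
        with pytest.raises(IndexError):
            move_control_point(cps, 6, (0.0, 0.0))


class TestContourValidation:
    def test_rejects_fewer_than_three_points(self):
        with pytest.raises(ValueError):
            Contour([(0, 0), (1, 1)])

    def test_rejects_consecutive_duplicates(self):
        with pytest.raises(ValueError):
            Contour([(0, 0), (0, 0), (1, 1), (2, 0)])

    def test_length_includes_closing_segment(self):
        tri = Contour([(0.0, 0.0), (3.0, 0.0), (3.0, 4.0)])
        assert tri.length == pytest.approx(3 + 4 + 5)

    def test_control_point_set_bounds(self, rng):
        pts = rng.normal(size=(31, 2))
        with pytest.raises(ValueError):
            ControlPointSet(pts, pts)


class TestSerialization:
    def test_json_roundtrip(self, tmp_path):
        contour = circle_contour(n=50)
        path = tmp_path / "c.json"
        save_contour(contour, path)
        data = json.loads(path.read_text())
        assert data["closed"] is True
        loaded = load_contour(path)
        np.testing.assert_array_equal(loaded.points, contour.points)

    @pytest.mark.parametrize("header", [True, False])
    def test_csv_roundtrip_header_optional(self, tmp_path, header):
        contour = circle_contour(n=10)
        path = tmp_path / "c.csv"
        save_contour(contour, path)
        if not header:
            lines = path.read_text().splitlines()[1:]
            path.write_text("\n".join(lines) + "\n")
        loaded = load_contour(path)
        np.testing.assert_allclose(loaded.points, contour.points)
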