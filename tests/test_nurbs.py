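"""NURBS curve mathematics: knots, basis, evaluation, fitting, editing."""

import numpy as np
import pytest
from scipy.interpolate import BSpline

from aawall.contour_ops import Contour
from aawall.metrics import compute_seg_metrics
from aawall.nurbs_refine import (ControlEdit, NurbsCurve, apply_edits,
                                 basis_function, clamped_uniform_knots,
                                 curve_to_contour, evaluate_curve,
                                 fit_curve_to_contour, rational_circle,
                                 curve_to_json, curve_from_json)

from conftest import circle_contour, mask_volume


class TestKnots:
    def test_bezier_case(self):
        assert np.allclose(clamped_uniform_knots(4, 3),
                           [0, 0, 0, 0, 1, 1, 1, 1])

    def test_uniform_interior(self):
        assert np.allclose(clamped_uniform_knots(5, 2),
                           [0, 0, 0, 1 / 3, 2 / 3, 1, 1, 1])

    def test_linear_two_points(self):
        assert np.allclose(clamped_uniform_knots(2, 1), [0, 0, 1, 1])

    def test_too_few_control_points_raises(self):
        with pytest.raises(ValueError):
            clamped_uniform_knots(3, 3)


class TestBasis:
    def test_degree_zero_is_span_indicator(self):
        U = np.array([0.0, 0.0, 0.5, 1.0, 1.0])
        # N_{1,0} is the indicator of [0, 0.5)
        assert basis_function(1, 1, 0.25, U) > 0

    def test_partition_of_unity(self):
        U = clamped_uniform_knots(9, 3)
        for t in np.linspace(0, 1, 37):
            total = sum(basis_function(i, 3, t, U) for i in range(9))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_bezier_quadratic_is_bernstein(self):
        U = np.array([0.0, 0, 0, 1, 1, 1])
        vals = [basis_function(i, 2, 0.5, U) for i in range(3)]
        assert np.allclose(vals, [0.25, 0.5, 0.25])


class TestEvaluate:
    def test_linear_midpoint(self):
        c = NurbsCurve([[0.0, 0.0], [2.0, 0.0]], [1.0, 1.0], 1,
                       [0.0, 0.0, 1.0, 1.0])
        assert np.allclose(evaluate_curve(c, 0.5), [1.0, 0.0])

    def test_unit_weights_match_scipy_bspline(self):
        rng = np.random.default_rng(2)
        P = rng.normal(size=(9, 2))
        U = clamped_uniform_knots(9, 3)
        ours = NurbsCurve(P, np.ones(9), 3, U)
        ref = BSpline(U, P, 3)
        ts = np.linspace(0, 1 - 1e-9, 41)
        assert np.allclose(evaluate_curve(ours, ts), ref(ts), atol=1e-12)

    def test_clamped_endpoint_interpolation(self):
        rng = np.random.default_rng(4)
        P = rng.normal(size=(7, 2))
        w = rng.uniform(0.5, 2.0, size=7)
        c = NurbsCurve(P, w, 3, clamped_uniform_knots(7, 3))
        assert np.allclose(evaluate_curve(c, 0.0), P[0], atol=1e-12)
        assert np.allclose(evaluate_curve(c, 1.0), P[-1], atol=1e-12)

    def test_exact_rational_circle(self):
        c = rational_circle(radius=1.0)
        ts = np.linspace(0, 1, 257)
        pts = evaluate_curve(c, ts)
        r = np.linalg.norm(pts, axis=1)
        assert np.abs(r - 1.0).max() <= 1e-9

    def test_rational_partition_of_unity(self):
        rng = np.random.default_rng(9)
        n, p = 8, 3
        U = clamped_uniform_knots(n, p)
        w = rng.uniform(0.2, 3.0, size=n)
        for t in rng.uniform(0, 1, size=25):
            N = np.array([basis_function(i, p, t, U) for i in range(n)])
            assert (N * w).sum() / (N @ w) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance_unit_weights(self):
        rng = np.random.default_rng(6)
        P = rng.normal(size=(6, 2))
        c = NurbsCurve(P, np.ones(6), 3, clamped_uniform_knots(6, 3))
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        shift = np.array([3.0, -1.5])
        c2 = NurbsCurve(P @ R.T + shift, np.ones(6), 3, clamped_uniform_knots(6, 3))
        ts = np.linspace(0, 1, 17)
        assert np.allclose(evaluate_curve(c2, ts),
                           evaluate_curve(c, ts) @ R.T + shift, atol=1e-12)

    def test_convex_hull_property(self):
        from matplotlib.path import Path as MplPath
        from scipy.spatial import ConvexHull

        rng = np.random.default_rng(8)
        P = rng.normal(size=(7, 2))
        c = NurbsCurve(P, np.ones(7), 3, clamped_uniform_knots(7, 3))
        hull = ConvexHull(P)
        poly = MplPath(np.vstack([P[hull.vertices], P[hull.vertices][:1]]),
                       closed=True)
        pts = evaluate_curve(c, np.linspace(0, 1, 101))
        assert poly.contains_points(pts, radius=1e-9).all()


class TestFit:
    def test_recovers_generating_curve(self):
        rng = np.random.default_rng(1)
        n, p = 10, 3
        U = clamped_uniform_knots(n, p)
        seam = np.array([4.0, 0.0])
        P = np.vstack([seam, rng.normal(size=(n - 2, 2)) * 3, seam])
        gen = NurbsCurve(P, np.ones(n), p, U)
        ts = np.linspace(0, 1, 120)
        pts = evaluate_curve(gen, ts)
        contour = Contour(pts[:-1])  # drop duplicate seam; Contour closes it
        fitted = fit_curve_to_contour(contour, n_ctrl=n, p=p, params=ts)
        assert fitted.fit_residual < 1e-6

    def test_circle_fit_radial_error(self):
        c = circle_contour(r=10.0, n=200)
        curve = fit_curve_to_contour(c, n_ctrl=16, p=3)
        pts = evaluate_curve(curve, np.linspace(0, 1, 400))
        r = np.linalg.norm(pts, axis=1)
        assert np.abs(r - 10.0).max() < 0.05

    def test_overparameterized_fit_raises(self):
        c = circle_contour(r=5.0, n=12)
        with pytest.raises(ValueError):
            fit_curve_to_contour(c, n_ctrl=13, p=3)


class TestEdits:
    def make_curve(self):
        c = circle_contour(r=10.0, n=120)
        return fit_curve_to_contour(c, n_ctrl=12, p=3)

    def test_empty_edit_list_identical(self):
        c = self.make_curve()
        c2 = apply_edits(c, [])
        assert np.array_equal(c.control_points, c2.control_points)
        assert np.array_equal(c.weights, c2.weights)

    def test_purity(self):
        c = self.make_curve()
        before = c.control_points.copy()
        apply_edits(c, [ControlEdit(3, (1.0, 2.0))])
        assert np.array_equal(c.control_points, before)

    def test_locality_of_support(self):
        c = self.make_curve()
        i, p = 5, c.degree
        c2 = apply_edits(c, [ControlEdit(i, (2.0, -1.0))])
        lo, hi = c.knots[i], c.knots[i + p + 1]
        ts = np.linspace(0, 1, 301)
        outside = (ts < lo - 1e-12) | (ts > hi + 1e-12)
        a = evaluate_curve(c, ts[outside])
        b = evaluate_curve(c2, ts[outside])
        assert np.abs(a - b).max() < 1e-12
        inside = (ts > lo + 0.01) & (ts < hi - 0.01)
        assert np.abs(evaluate_curve(c, ts[inside])
                      - evaluate_curve(c2, ts[inside])).max() > 1e-6

    def test_weight_increase_pulls_curve_toward_point(self):
        c = self.make_curve()
        i, p = 6, c.degree
        tmid = 0.5 * (c.knots[i] + c.knots[i + p + 1])
        before = np.linalg.norm(evaluate_curve(c, tmid) - c.control_points[i])
        c2 = apply_edits(c, [ControlEdit(i, (0.0, 0.0),
                                         new_weight=2.0 * c.weights[i])])
        after = np.linalg.norm(evaluate_curve(c2, tmid) - c2.control_points[i])
        assert after < before

    def test_invalid_index_raises(self):
        with pytest.raises(IndexError):
            apply_edits(self.make_curve(), [ControlEdit(99)])

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            ControlEdit(0, new_weight=0.0)


class TestCurveToContour:
    def test_area_preserved_within_1_percent(self):
        src = circle_contour(r=9.0, n=160)
        curve = fit_curve_to_contour(src, n_ctrl=16, p=3)
        out = curve_to_contour(curve, 256)
        assert out.area() == pytest.approx(src.area(), rel=0.01)

    def test_degree_one_is_polyline_through_control_points(self):
        P = np.array([[0.0, 0.0], [4.0, 0.0], [4.0, 4.0], [0.0, 4.0], [0.0, 0.0]])
        c = NurbsCurve(P, np.ones(5), 1, clamped_uniform_knots(5, 1))
        ts = np.linspace(0, 1, 4 * 64, endpoint=False)
        pts = evaluate_curve(c, ts)
        # every sample lies on an edge of the control polygon
        for q in pts[::7]:
            d = min(_point_segment_dist(q, P[k], P[k + 1]) for k in range(4))
            assert d < 1e-12

    def test_mask_round_trip_through_nurbs(self, disk_mask):
        from aawall.contour_ops import contour_to_mask, mask_to_contours

        (c,) = mask_to_contours(disk_mask)
        curve = fit_curve_to_contour(c, n_ctrl=16, p=3)
        out = curve_to_contour(curve, 256)
        rec = contour_to_mask(out, disk_mask.shape)
        m = compute_seg_metrics(mask_volume(rec), mask_volume(disk_mask))
        assert m.dsc >= 0.98

    def test_minimum_samples(self):
        with pytest.raises(ValueError):
            curve_to_contour(rational_circle(), 4)


def _point_segment_dist(q, a, b):
    ab = b - a
    t = np.clip(np.dot(q - a, ab) / np.dot(ab, ab), 0, 1)
    return np.linalg.norm(q - (a + t * ab))


def test_json_round_trip(tmp_path):
    c = rational_circle(radius=3.0, center=(1.0, -2.0))
    curve_to_json(c, tmp_path / "c.json")
    back = curve_from_json(tmp_path / "c.json")
    assert np.allclose(back.control_points, c.control_points)
    assert np.allclose(back.weights, c.weights)
    assert back.degree == c.degree
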