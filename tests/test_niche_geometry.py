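"""Standard-ellipse fitting, scaling, intersection and overlap."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from sulaniche.niche_geometry import (
    DegenerateGeometryError,
    InsufficientSampleError,
    ScaledEllipse,
    ellipse_polygon,
    fit_ellipse,
    intersection_area,
    overlap_index,
    scale_ellipse,
)

DIAMOND = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])


def circle(cx, cy, r=1.0):
    return ScaledEllipse(center=(cx, cy), semi_major=r, semi_minor=r,
                         orientation=0.0, scale_mode="standard")


def lens_area(d, r=1.0):
    """Closed-form intersection area of two radius-r circles d apart."""
    if d >= 2 * r:
        return 0.0
    return 2 * r**2 * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r**2 - d**2)


class TestFitEllipse:
    def test_diamond_worked_example(self):
        e = fit_ellipse(DIAMOND)
        assert e.centroid == pytest.approx((0.0, 0.0))
        assert np.asarray(e.covariance) == pytest.approx(np.diag([2 / 3, 2 / 3]))
        assert e.sea == pytest.approx(2 * math.pi / 3, rel=1e-12)
        assert e.seac == pytest.approx(math.pi, rel=1e-12)

    def test_seac_sea_ratio_is_exact_small_sample_correction(self):
        rng = np.random.default_rng(0)
        for n in (3, 5, 8, 20, 50):
            e = fit_ellipse(rng.normal(size=(n, 2)))
            assert e.seac / e.sea == pytest.approx((n - 1) / (n - 2), rel=1e-14)

    def test_collinear_points_degenerate_zero_area(self):
        e = fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert e.degenerate
        assert e.eigenvalues[1] == pytest.approx(0.0, abs=1e-12)
        assert e.sea == pytest.approx(0.0, abs=1e-12)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientSampleError):
            fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0]]))

    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50),
        theta=st.floats(0, 2 * math.pi), scale=st.floats(0.1, 10),
    )
    def test_sea_invariant_to_rigid_motion_and_scales_quadratically(self, dx, dy, theta, scale):
        rng = np.random.default_rng(42)
        xy = rng.normal(size=(12, 2)) @ np.array([[1.0, 0.4], [0.0, 0.7]])
        base = fit_ellipse(xy).sea
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        moved = xy @ rot.T + np.array([dx, dy])
        assert fit_ellipse(moved).sea == pytest.approx(base, rel=1e-9)
        assert fit_ellipse(xy * scale).sea == pytest.approx(base * scale**2, rel=1e-9)


class TestScaleEllipse:
    def test_probability_level_matching_standard_ellipse(self):
        # chi2(2df) quantile equals 1 at p = 1 - exp(-1/2)
        e = fit_ellipse(DIAMOND)
        p = 1 - math.exp(-0.5)
        se = scale_ellipse(e, "probability", p=p)
        std = scale_ellipse(e, "standard")
        assert se.semi_major == pytest.approx(std.semi_major, rel=1e-12)

    def test_p95_scale_factor(self):
        e = fit_ellipse(DIAMOND)
        se = scale_ellipse(e, "probability", p=0.95)
        assert se.semi_major / math.sqrt(e.eigenvalues[0]) == pytest.approx(
            math.sqrt(5.991), abs=1e-3)

    def test_seac_mode_at_n3_scales_axes_by_sqrt2(self):
        e = fit_ellipse(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]))
        se = scale_ellipse(e, "seac")
        assert se.area / e.sea == pytest.approx(2.0, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_probability_outside_unit_interval_rejected(self, p):
        with pytest.raises(ValueError):
            scale_ellipse(fit_ellipse(DIAMOND), "probability", p=p)

    def test_degenerate_ellipse_rejected(self):
        e = fit_ellipse(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        with pytest.raises(DegenerateGeometryError):
            scale_ellipse(e, "standard")


class TestIntersection:
    def test_identical_unit_circles(self):
        a = circle(0, 0)
        assert intersection_area(a, a) == pytest.approx(math.pi, rel=1e-4)

    def test_unit_circles_one_apart_match_lens_formula(self):
        got = intersection_area(circle(0, 0), circle(1, 0))
        assert got == pytest.approx(lens_area(1.0), abs=1e-4)
        assert round(got, 4) == 1.2284

    def test_disjoint_circles(self):
        assert intersection_area(circle(0, 0), circle(10, 0)) == 0.0

    def test_symmetric_in_arguments(self):
        a = ScaledEllipse((0, 0), 2.0, 1.0, 0.3, "standard")
        b = ScaledEllipse((1, 0.5), 1.5, 0.7, 1.2, "standard")
        assert intersection_area(a, b) == pytest.approx(intersection_area(b, a), rel=1e-12)

    def test_containment_gives_smaller_area(self):
        outer = ScaledEllipse((0, 0), 4.0, 2.0, 0.5, "standard")
        inner = ScaledEllipse((0, 0), 2.0, 1.0, 0.5, "standard")
        got = intersection_area(outer, inner)
        assert got == pytest.approx(inner.area, rel=1e-4)

    def test_monte_carlo_agrees_with_polygonal(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            a = ScaledEllipse(tuple(rng.uniform(-1, 1, 2)), rng.uniform(0.5, 2),
                              rng.uniform(0.3, 1.5), rng.uniform(0, math.pi), "standard")
            b = ScaledEllipse(tuple(rng.uniform(-1, 1, 2)), rng.uniform(0.5, 2),
                              rng.uniform(0.3, 1.5), rng.uniform(0, math.pi), "standard")
            poly = intersection_area(a, b)
            mc = intersection_area(a, b, method="monte_carlo", seed=seed)
            assert mc == pytest.approx(poly, abs=0.01 * min(a.area, b.area))


class TestOverlapIndex:
    def test_self_overlap_is_one(self):
        a = ScaledEllipse((0, 0), 2.0, 1.0, 0.7, "standard")
        assert overlap_index(a, a).jaccard == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_overlap_is_zero(self):
        assert overlap_index(circle(0, 0), circle(10, 0)).jaccard == 0.0

    def test_unit_circles_one_apart_jaccard(self):
        res = overlap_index(circle(0, 0), circle(1, 0))
        expected = lens_area(1.0) / (2 * math.pi - lens_area(1.0))
        assert res.jaccard == pytest.approx(expected, abs=1e-4)
        assert round(res.jaccard, 4) == 0.2430
        assert res.percent == pytest.approx(100 * res.jaccard)

    @given(
        cx=st.floats(-2, 2), cy=st.floats(-2, 2),
        a1=st.floats(0.3, 2), b1=st.floats(0.3, 2),
        th=st.floats(0, math.pi),
    )
    def test_jaccard_in_unit_interval_and_symmetric(self, cx, cy, a1, b1, th):
        e1 = ScaledEllipse((0.0, 0.0), 1.5, 0.8, 0.2, "standard")
        e2 = ScaledEllipse((cx, cy), max(a1, b1), min(a1, b1), th, "standard")
        r12 = overlap_index(e1, e2)
        r21 = overlap_index(e2, e1)
        assert 0.0 <= r12.jaccard <= 1.0
        assert r12.jaccard == pytest.approx(r21.jaccard, abs=1e-12)
        assert r12.intersection <= min(r12.area_1, r12.area_2) + 1e-12

    def test_polygon_approximation_close_to_true_area(self):
        a = circle(0, 0)
        assert ellipse_polygon(a, 720).area == pytest.approx(math.pi, rel=1e-4)
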