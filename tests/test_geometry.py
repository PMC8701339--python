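"""Polygon geometry: centroids, clock angles, half cut-throughs, overlap."""

import numpy as np
import pytest

from onh360.geometry import (
    Centroid,
    CentroidMethod,
    SelfIntersectionError,
    angle_of,
    close_gaps,
    half_cut_throughs,
    overlap_area,
    polygon_area,
    polygon_centroid,
)

from conftest import circle_polygon, raster_overlap_oracle, resampling_oracle_radii, star_polygon, square


class TestCloseGaps:
    def test_open_triangle_gets_closing_vertex(self):
        v = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        out = close_gaps(v)
        np.testing.assert_array_equal(out, np.vstack([v, v[:1]]))

    def test_already_closed_square_unchanged(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
        np.testing.assert_array_equal(close_gaps(sq), sq)

    def test_consecutive_duplicates_collapsed(self):
        v = np.array([[0.0, 0.0], [0.0, 0.0], [4.0, 0.0], [4.0, 0.0], [0.0, 3.0]])
        assert close_gaps(v).shape == (4, 2)

    def test_two_distinct_points_raise(self):
        with pytest.raises(ValueError, match="distinct"):
            close_gaps(np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]]))


class TestAreaCentroid:
    def test_unit_square(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert polygon_area(sq) == pytest.approx(1.0)
        c = polygon_centroid(sq)
        assert (c.x, c.y) == pytest.approx((0.5, 0.5))

    def test_right_triangle_closed_form(self):
        tri = np.array([[0.0, 0.0], [6.0, 0.0], [0.0, 6.0]])
        assert polygon_area(tri) == pytest.approx(18.0)
        c = polygon_centroid(tri)
        assert (c.x, c.y) == pytest.approx((2.0, 2.0))

    def test_self_intersecting_bowtie_raises(self):
        bow = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        with pytest.raises(SelfIntersectionError):
            polygon_area(bow)

    def test_raster_matches_analytic_on_random_polygons(self):
        # raster mask at 4x supersampling vs exact first-moment centroid;
        # a 16x raster serves as ground truth for the raster path itself
        rng = np.random.default_rng(5)
        for _ in range(10):
            poly = star_polygon(rng, n_vertices=16, base=12.0, amp=0.3, center=(30, 30))
            exact = polygon_centroid(poly, CentroidMethod.ANALYTIC)
            r4 = polygon_centroid(poly, CentroidMethod.RASTER, supersample=4)
            r16 = polygon_centroid(poly, CentroidMethod.RASTER, supersample=16)
            assert np.hypot(r4.x - exact.x, r4.y - exact.y) < 0.5
            assert np.hypot(r16.x - exact.x, r16.y - exact.y) < np.hypot(
                r4.x - exact.x, r4.y - exact.y
            ) + 0.05

    def test_scale_equivariance(self):
        rng = np.random.default_rng(7)
        poly = star_polygon(rng, base=3.0, center=(10, 10))
        a1 = polygon_area(poly)
        assert polygon_area(poly * 2.5) == pytest.approx(a1 * 2.5**2, rel=1e-12)


class TestAngleOf:
    @pytest.mark.parametrize(
        "point,expected",
        [((0, -5), 0.0), ((5, 0), 90.0), ((0, 5), 180.0), ((-5, 0), 270.0),
         ((5, -5), 45.0)],
    )
    def test_clock_anchors(self, point, expected):
        # 12 o'clock = 0 deg, clockwise: 3 o'clock 90, 6 o'clock 180, 9 o'clock 270
        assert angle_of(point, (0.0, 0.0)) == pytest.approx(expected)

    def test_origin_coincidence_raises(self):
        with pytest.raises(ValueError):
            angle_of((1.0, 1.0), (1.0, 1.0))

    def test_range_half_open(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.normal(size=2)
            a = angle_of(p, (0.0, 0.0))
            assert 0.0 <= a < 360.0


class TestHalfCutThroughs:
    ORIGIN = Centroid(0.0, 0.0)

    def test_circle_gives_constant_radius(self):
        poly = circle_polygon((0.0, 0.0), 10.0, n=720)
        prof = half_cut_throughs(poly, self.ORIGIN)
        assert np.abs(prof.radii - 10.0).max() < 1e-3
        assert not prof.non_star_shaped

    def test_square_closed_form(self):
        sq = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
        prof = half_cut_throughs(sq, self.ORIGIN)
        assert prof.radii[0] == pytest.approx(1.0)
        assert prof.radii[45] == pytest.approx(np.sqrt(2.0))
        assert prof.radii[90] == pytest.approx(1.0)

    def test_matches_dense_resampling_oracle(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            poly = star_polygon(rng, n_vertices=rng.integers(8, 40), base=1.0, amp=0.35)
            prof = half_cut_throughs(poly, self.ORIGIN)
            oracle = resampling_oracle_radii(poly, (0.0, 0.0))
            worst = max(worst, np.abs(prof.radii - oracle).max())
        assert worst < 1e-6

    def test_origin_outside_raises(self):
        sq = np.array([[1.0, 1.0], [2.0, 1.0], [2.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="outside"):
            half_cut_throughs(sq, Centroid(0.0, 0.0))

    def test_non_star_shape_flagged_and_farthest_kept(self):
        # square with a horizontal slot reaching past the origin's azimuth:
        # the upward ray from (0, 2) exits at y=0.5, re-enters at y=-0.5
        # and finally exits at y=-3, so it crosses the boundary 3 times
        poly = np.array(
            [[-3.0, -3.0], [3.0, -3.0], [3.0, -0.5], [-1.0, -0.5],
             [-1.0, 0.5], [3.0, 0.5], [3.0, 3.0], [-3.0, 3.0]]
        )
        prof = half_cut_throughs(poly, Centroid(0.0, 2.0))
        assert prof.non_star_shaped
        assert 0 in prof.flagged_degrees
        assert prof.radii[0] == pytest.approx(5.0)  # farthest crossing kept
        assert prof.radii[180] == pytest.approx(1.0)  # star-shaped direction

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(9)
        poly = circle_polygon((0, 0), 1.0, n=3600) * (1 + 0)
        # wavy star sampled exactly at degree grid multiples
        theta = np.radians(np.arange(0, 360, 0.1))
        r = 1 + 0.2 * np.cos(4 * theta)
        poly = np.column_stack([r * np.sin(theta), -r * np.cos(theta)])
        prof = half_cut_throughs(poly, self.ORIGIN)
        k = 90
        rot = np.radians(k)
        rotm = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        # clockwise rotation by k degrees in y-down screen coords
        poly_rot = poly @ rotm
        prof_rot = half_cut_throughs(poly_rot, self.ORIGIN)
        np.testing.assert_allclose(prof_rot.radii, np.roll(prof.radii, k), rtol=1e-6)

    def test_translation_invariance(self):
        rng = np.random.default_rng(10)
        poly = star_polygon(rng, base=2.0)
        prof = half_cut_throughs(poly, self.ORIGIN)
        shift = np.array([123.4, -56.7])
        prof2 = half_cut_throughs(poly + shift, Centroid(*shift))
        np.testing.assert_allclose(prof2.radii, prof.radii, rtol=1e-9, atol=1e-9)

    def test_angle_of_consistency_with_ray(self):
        rng = np.random.default_rng(11)
        poly = star_polygon(rng, base=5.0)
        prof = half_cut_throughs(poly, self.ORIGIN)
        for d in (0, 37, 90, 181, 270, 359):
            r = prof.radii[d]
            pt = (r * np.sin(np.radians(d)), -r * np.cos(np.radians(d)))
            assert angle_of(pt, (0.0, 0.0)) == pytest.approx(d, abs=1e-9)


class TestOverlap:
    def test_identical_squares(self):
        sq = square(0, 0, 0.5)
        assert overlap_area(sq, sq) == pytest.approx(1.0)

    def test_offset_unit_squares(self):
        a = square(0.5, 0.5, 0.5)
        b = square(1.0, 0.5, 0.5)
        assert overlap_area(a, b) == pytest.approx(0.5)

    def test_disjoint_is_zero(self):
        assert overlap_area(square(0, 0, 0.5), square(5, 5, 0.5)) == 0.0

    def test_nested_equals_inner_area(self):
        outer = square(0, 0, 2.0)
        inner = square(0.3, -0.2, 0.5)
        assert overlap_area(outer, inner) == pytest.approx(polygon_area(inner))

    def test_matches_raster_oracle_on_convex_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            # random convex polygons: convex hull of random points
            from scipy.spatial import ConvexHull

            pts_a = rng.uniform(0, 2, (14, 2))
            pts_b = rng.uniform(0.5, 2.5, (14, 2))
            pa = pts_a[ConvexHull(pts_a).vertices]
            pb = pts_b[ConvexHull(pts_b).vertices]
            exact = overlap_area(pa, pb)
            approx = raster_overlap_oracle(pa, pb, step=0.004)
            ref = max(exact, 1e-3)
            assert abs(exact - approx) / ref < 0.01 or abs(exact - approx) < 2e-4
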