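"""Boundary geometry: contour extraction, hinge clipping, curvature,
curvature-adaptive polygon placement."""

import numpy as np
import pytest

from discmorph.boundary import (
    BoundaryPolygon,
    Contour,
    HingeAnchors,
    clean_mask,
    clip_hinge,
    contour_arclengths,
    curvature_profile,
    extract_contour,
    place_polygon_vertices,
    wing_area,
)
from discmorph.errors import ContourError, MaskError


def disk_mask(radius=50, size=128):
    y, x = np.mgrid[0:size, 0:size]
    c = size / 2
    return (x - c) ** 2 + (y - c) ** 2 <= radius**2


def circle_contour(radius=60.0, n=720):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return Contour(np.c_[100 + radius * np.cos(t), 100 + radius * np.sin(t)])


class TestExtractContour:
    def test_square_perimeter(self):
        m = np.zeros((20, 20), bool)
        m[6:14, 6:14] = True
        c = extract_contour(m)
        per = contour_arclengths(c.points)[-1] + np.linalg.norm(c.points[0] - c.points[-1])
        assert per == pytest.approx(32, abs=2)

    def test_enclosed_area_matches_pixel_count(self, single_wing):
        m, _ = clean_mask(single_wing.mask)
        c = extract_contour(m)
        assert abs(c.signed_area) == pytest.approx(wing_area(m), rel=0.01)

    def test_orientation_is_ccw_even_for_flipped_mask(self):
        m = disk_mask()
        for mm in (m, m[::-1], m[:, ::-1]):
            assert extract_contour(mm).signed_area > 0

    def test_contour_point_spacing(self):
        c = extract_contour(disk_mask())
        seg = np.linalg.norm(np.roll(c.points, -1, axis=0) - c.points, axis=1)
        assert seg.max() <= 2.0

    def test_two_components_rejected_with_count(self):
        m = np.zeros((30, 30), bool)
        m[5:10, 5:10] = True
        m[20:25, 20:25] = True
        with pytest.raises(MaskError, match="2"):
            extract_contour(m)

    def test_empty_and_holey_masks_rejected(self):
        with pytest.raises(MaskError):
            extract_contour(np.zeros((10, 10), bool))
        m = disk_mask()
        m[60:66, 60:66] = False
        with pytest.raises(MaskError, match="hole"):
            extract_contour(m)

    def test_clean_mask_pads_border_contact(self):
        m = np.zeros((20, 20), bool)
        m[0:10, 5:15] = True  # touches top border
        cleaned, (dr, dc) = clean_mask(m)
        assert (dr, dc) == (5, 5)
        assert not cleaned[0, :].any()
        assert cleaned.sum() == m.sum()


class TestClipHinge:
    def test_circle_quarter_removed(self):
        c = circle_contour()
        # anchors 90 degrees apart on the circle
        a = HingeAnchors(humeral=(160.0, 100.0), alula=(100.0, 160.0))
        out = clip_hinge(c, a)
        per_in = 2 * np.pi * 60
        per_out = contour_arclengths(out.points)[-1] + np.linalg.norm(
            out.points[0] - out.points[-1]
        )
        expected = 0.75 * per_in + 60 * np.sqrt(2)
        assert per_out == pytest.approx(expected, abs=2.0)

    def test_synthetic_wing_clip_length(self, single_wing):
        m, _ = clean_mask(single_wing.mask)
        c = extract_contour(m)
        out = clip_hinge(c, single_wing.anchors)
        assert out.is_simple()
        per_out = contour_arclengths(out.points)[-1]
        per_in = contour_arclengths(c.points)[-1]
        assert per_out < per_in  # hinge arc replaced by a shorter chord

    def test_idempotent(self, single_wing):
        m, _ = clean_mask(single_wing.mask)
        c = extract_contour(m)
        once = clip_hinge(c, single_wing.anchors)
        twice = clip_hinge(once, single_wing.anchors)
        assert abs(len(twice) - len(once)) <= 1
        per1 = contour_arclengths(once.points)[-1]
        per2 = contour_arclengths(twice.points)[-1]
        assert per2 == pytest.approx(per1, abs=2.0)

    def test_identical_anchors_rejected(self):
        c = circle_contour()
        with pytest.raises(ContourError):
            clip_hinge(c, HingeAnchors(humeral=(160.0, 100.0), alula=(160.0, 100.0)))

    def test_far_anchor_rejected(self):
        c = circle_contour()
        with pytest.raises(ContourError, match="px"):
            clip_hinge(c, HingeAnchors(humeral=(100.0, 100.0), alula=(160.0, 100.0)))


class TestCurvature:
    def test_circle_curvature_is_one_over_r(self):
        c = circle_contour(radius=50.0, n=600)
        k = curvature_profile(c)
        assert np.median(k) == pytest.approx(0.02, rel=0.1)

    def test_straight_runs_have_negligible_curvature(self):
        # rectangle traced at 1 px spacing
        pts = []
        for x in range(0, 100):
            pts.append((x, 0))
        for y in range(0, 40):
            pts.append((100, y))
        for x in range(100, 0, -1):
            pts.append((x, 40))
        for y in range(40, 0, -1):
            pts.append((0, y))
        c = Contour(np.array(pts, float)).oriented_ccw()
        k = curvature_profile(c)
        s = np.arange(len(pts))
        # points well inside the long edges
        interior_edge = (s > 20) & (s < 80)
        assert k[interior_edge].max() < 1e-3

    def test_ellipse_max_curvature(self):
        t = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        c = Contour(np.c_[100 * np.cos(t), 50 * np.sin(t)])
        k = curvature_profile(c)
        assert k.max() == pytest.approx(100 / 50**2, rel=0.1)

    def test_small_window_rejected(self):
        with pytest.raises(ContourError):
            curvature_profile(circle_contour(), window=1)


class TestPlacePolygonVertices:
    def test_constant_curvature_gives_equal_arclength(self):
        c = circle_contour(radius=60.0, n=720)
        k = np.full(len(c), 1 / 60.0)
        poly = place_polygon_vertices(c, k, 36)
        seg = np.abs(np.roll(poly.vertices, -1) - poly.vertices)
        expected = 2 * np.pi * 60 / 36
        assert np.allclose(seg, expected, atol=1.0)

    def test_corner_density_on_l_shape(self):
        # L-shaped contour traced at 0.5 px spacing
        corners = [(0, 0), (60, 0), (60, 30), (30, 30), (30, 60), (0, 60)]
        pts = []
        for i in range(len(corners)):
            a = np.array(corners[i], float)
            b = np.array(corners[(i + 1) % len(corners)], float)
            n = int(np.linalg.norm(b - a) * 2)
            for t in np.linspace(0, 1, n, endpoint=False):
                pts.append(a + t * (b - a))
        c = Contour(np.array(pts)).oriented_ccw()
        k = curvature_profile(c)
        poly = place_polygon_vertices(c, k, 40)
        v = np.c_[poly.vertices.real, poly.vertices.imag]
        near_corner = np.zeros(len(v), bool)
        for cn in corners:
            near_corner |= np.linalg.norm(v - np.array(cn, float), axis=1) < 5
        corner_arclen = len(corners) * 10.0  # 5 px each side of 6 corners
        total_arclen = 2 * (60 + 30 + 30 + 60 + 30 + 60) / 2.0
        straight_arclen = 240.0 - corner_arclen
        dens_corner = near_corner.sum() / corner_arclen
        dens_straight = (~near_corner).sum() / straight_arclen
        assert dens_corner >= 2 * dens_straight

    def test_beats_uniform_placement_on_wing(self, single_wing):
        import shapely

        m, _ = clean_mask(single_wing.mask)
        c = clip_hinge(extract_contour(m), single_wing.anchors)
        k = curvature_profile(c)
        adaptive = place_polygon_vertices(c, k, 60)
        uniform = place_polygon_vertices(c, np.ones(len(c)), 60)
        pts = shapely.points(c.points)

        def hausdorff(poly):
            ring = shapely.LinearRing(np.c_[poly.vertices.real, poly.vertices.imag])
            return shapely.distance(ring, pts).max()

        assert hausdorff(adaptive) < hausdorff(uniform)

    def test_angle_sum_invariant(self, single_wing):
        m, _ = clean_mask(single_wing.mask)
        c = clip_hinge(extract_contour(m), single_wing.anchors)
        poly = place_polygon_vertices(c, curvature_profile(c), 50)
        assert np.sum(np.pi - poly.interior_angles) == pytest.approx(2 * np.pi, abs=1e-6)
        assert np.all(poly.interior_angles > 0)
        assert np.all(poly.interior_angles < 2 * np.pi)

    def test_too_many_vertices_rejected(self):
        c = circle_contour(n=100)
        with pytest.raises(ContourError):
            place_polygon_vertices(c, np.ones(100), 101)


class TestWingArea:
    def test_square_and_empty(self):
        m = np.zeros((12, 12), bool)
        m[1:11, 1:11] = True
        assert wing_area(m) == 100
        assert wing_area(np.zeros((5, 5), bool)) == 0

    def test_generator_bookkeeping(self, single_wing):
        assert wing_area(single_wing.mask) == single_wing.truth["area"]
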