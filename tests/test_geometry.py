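"""Unit and property tests for per-bleb morphometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely import contains_xy

import blebmorph as bm
from blebmorph import (
    BlebOutline,
    PlanarPoint,
    ValidationError,
)

from conftest import make_ellipse_polygon, star_polygon


def mc_area_fraction(outline, rng, n_points=200_000):
    """Monte-Carlo point-in-polygon area estimate and its standard error."""
    verts = outline.vertices
    lo, hi = verts.min(axis=0), verts.max(axis=0)
    box_area = np.prod(hi - lo)
    pts = rng.uniform(lo, hi, size=(n_points, 2))
    inside = contains_xy(outline.to_shapely(), pts[:, 0], pts[:, 1])
    p = inside.mean()
    return box_area * p, box_area * math.sqrt(p * (1 - p) / n_points)


class TestCanonicalize:
    def test_identity_when_already_canonical(self):
        o = make_ellipse_polygon(2, 1)
        ret = PlanarPoint(0.1, 0.2)
        out, r2, vs = bm.canonicalize(o, ret, 3.0, "+y")
        assert out is o and r2 is ret and vs == 3.0

    def test_image_frame_negates_y(self):
        o = make_ellipse_polygon(2, 1, center=(0, 1))
        out, r2, vs = bm.canonicalize(o, PlanarPoint(0.5, 2.0), 3.0, "-y")
        assert np.allclose(out.vertices[:, 1].mean(), -1.0, atol=1e-12)
        assert r2.y == -2.0 and vs == -3.0
        # winding preserved: outline still validates and area unchanged
        assert bm.polygon_area(out) == pytest.approx(bm.polygon_area(o))

    def test_missing_direction_is_configuration_error(self):
        o = make_ellipse_polygon(2, 1)
        with pytest.raises(bm.ConfigurationError):
            bm.canonicalize(o, PlanarPoint(0, 0), 3.0, "up")

    def test_degenerate_outline_rejected(self):
        with pytest.raises(ValidationError):
            BlebOutline([(0, 0), (1, 1)])


class TestPolygonArea:
    def test_unit_square(self):
        sq = BlebOutline([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert bm.polygon_area(sq) == 1.0

    def test_orientation_invariance(self):
        sq = BlebOutline([(0, 1), (1, 1), (1, 0), (0, 0)])
        assert bm.polygon_area(sq) == 1.0

    def test_self_intersecting_rejected(self):
        with pytest.raises(ValidationError):
            BlebOutline([(0, 0), (1, 1), (1, 0), (0, 1)])

    def test_256gon_matches_monte_carlo(self, rng):
        poly = make_ellipse_polygon(1, 1, n=256)
        est, se = mc_area_fraction(poly, rng)
        assert abs(bm.polygon_area(poly) - est) < 3 * se

    def test_random_star_polygons_match_monte_carlo(self, rng):
        for _ in range(10):
            poly = star_polygon(rng)
            est, se = mc_area_fraction(poly, rng, n_points=100_000)
            assert abs(bm.polygon_area(poly) - est) < 3 * se


class TestFitEllipse:
    def test_recovers_generating_ellipse(self):
        fit = bm.fit_ellipse(make_ellipse_polygon(2, 1, n=512))
        assert fit.a == pytest.approx(2.0, rel=0.01)
        assert fit.b == pytest.approx(1.0, rel=0.01)
        assert abs(fit.orientation) < 0.5
        assert abs(fit.center.x) < 0.01 and abs(fit.center.y) < 0.01

    def test_rotation_equivariance(self):
        base = bm.fit_ellipse(make_ellipse_polygon(2, 1, n=512))
        rot = bm.fit_ellipse(make_ellipse_polygon(2, 1, theta_deg=30, n=512))
        assert rot.orientation == pytest.approx(30.0, abs=0.1)
        assert rot.a == pytest.approx(base.a, rel=1e-9)
        assert rot.b == pytest.approx(base.b, rel=1e-9)

    def test_circle_is_isotropic(self):
        fit = bm.fit_ellipse(make_ellipse_polygon(1.5, 1.5, n=256))
        assert fit.a == pytest.approx(fit.b, rel=1e-6)
        assert -90 < fit.orientation <= 90

    def test_area_matching(self, rng):
        poly = star_polygon(rng)
        fit = bm.fit_ellipse(poly)
        assert math.pi * fit.a * fit.b == pytest.approx(
            bm.polygon_area(poly), rel=1e-9
        )

    @pytest.mark.parametrize("n_vertices", [256, 512])
    @pytest.mark.parametrize("a,b,theta", [(2, 1, 0), (3, 1.2, 70), (5, 4.9, -40)])
    def test_dense_sampling_within_one_percent(self, a, b, theta, n_vertices):
        fit = bm.fit_ellipse(make_ellipse_polygon(a, b, theta, n=n_vertices))
        assert fit.a == pytest.approx(a, rel=0.01)
        assert fit.b == pytest.approx(b, rel=0.01)
        assert fit.orientation == pytest.approx(theta, abs=1.0)


class TestVerticalExtents:
    def test_symmetric_ellipse_on_retinotomy(self):
        o = make_ellipse_polygon(2, 1)
        pp, pd = bm.vertical_extents(o, PlanarPoint(0, 0), 5.0)
        assert pp == pd
        assert bm.vertical_anisotropy(pp, pd) == 1.0

    def test_one_sided_bleb_has_zero_distal(self):
        o = BlebOutline([(0, 1), (2, 1), (2, 3), (0, 3)])
        with pytest.warns(bm.AnnotationWarning):
            pp, pd = bm.vertical_extents(o, PlanarPoint(1, 0), 10.0)
        assert pd == 0.0 and pp == 3.0
        assert bm.vertical_anisotropy(pp, pd) is None

    def test_square_spanning_retinotomy(self):
        o = BlebOutline([(0, -1), (2, -1), (2, 3), (0, 3)])
        pp, pd = bm.vertical_extents(o, PlanarPoint(1, 0), 10.0)
        assert (pp, pd) == (3.0, 1.0)
        # VS below instead: proximal/distal swap
        pp2, pd2 = bm.vertical_extents(o, PlanarPoint(1, 0), -10.0)
        assert (pp2, pd2) == (1.0, 3.0)

    def test_x_coordinates_ignored(self, rng):
        o = make_ellipse_polygon(2, 1)
        stretched = BlebOutline(o.vertices * np.array([7.0, 1.0]))
        assert bm.vertical_extents(o, PlanarPoint(0, 0.3), 5.0) == (
            bm.vertical_extents(stretched, PlanarPoint(0, 0.3), 5.0)
        )


class TestClassification:
    @pytest.mark.parametrize(
        "a_v,expected",
        [
            (1.0, "balanced"),
            (0.35, "away"),
            (1.23, "toward"),
            (0.9, "balanced"),
            (1.1, "balanced"),
            (0.8999, "away"),
            (1.1001, "toward"),
            (None, "undefined"),
        ],
    )
    def test_partition(self, a_v, expected):
        assert bm.classify_propagation(a_v) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            bm.classify_propagation(-0.1)


class TestAreaSplit:
    def test_square_centered_on_clip_line(self):
        o = BlebOutline([(0, -1), (1, -1), (1, 1), (0, 1)])
        ap, ad = bm.area_split(o, PlanarPoint(0.5, 0), 5.0)
        assert ap == pytest.approx(1.0) and ad == pytest.approx(1.0)
        assert bm.area_anisotropy(ap, ad) == pytest.approx(1.0)

    def test_entirely_proximal(self):
        o = BlebOutline([(0, 1), (1, 1), (1, 2), (0, 2)])
        with pytest.warns(bm.AnnotationWarning):
            bm.vertical_extents(o, PlanarPoint(0.5, 0), 5.0)
        ap, ad = bm.area_split(o, PlanarPoint(0.5, 0), 5.0)
        assert (ap, ad) == (1.0, 0.0)
        assert bm.area_anisotropy(ap, ad) is None

    def test_two_to_one_split(self):
        o = BlebOutline([(0, -1), (1, -1), (1, 2), (0, 2)])
        ap, ad = bm.area_split(o, PlanarPoint(0.5, 0), 5.0)
        assert bm.area_anisotropy(ap, ad) == pytest.approx(2.0)

    def test_random_polygons_match_monte_carlo_and_conserve(self, rng):
        for _ in range(10):
            poly = star_polygon(rng)
            ret = PlanarPoint(0.0, float(rng.uniform(-1, 1)))
            ap, ad = bm.area_split(poly, ret, 10.0)
            total = bm.polygon_area(poly)
            assert ap + ad == pytest.approx(total, rel=1e-9)
            verts = poly.vertices
            lo, hi = verts.min(axis=0), verts.max(axis=0)
            pts = rng.uniform(lo, hi, size=(100_000, 2))
            inside = contains_xy(poly.to_shapely(), pts[:, 0], pts[:, 1])
            prox = inside & (pts[:, 1] > ret.y)
            box = np.prod(hi - lo)
            p = prox.mean()
            se = box * math.sqrt(p * (1 - p) / len(pts))
            assert abs(ap - box * p) < 3 * se


class TestTilt:
    def test_horizontal_ellipse(self):
        fit = bm.fit_ellipse(make_ellipse_polygon(2, 1, n=512))
        assert bm.long_axis_tilt(fit) == pytest.approx(0.0, abs=0.5)

    def test_vertical_ellipse(self):
        fit = bm.fit_ellipse(make_ellipse_polygon(1, 2, n=512))
        assert bm.long_axis_tilt(fit) == pytest.approx(90.0, abs=0.5)

    def test_near_circular_gated_out(self):
        fit = bm.EllipseFit(PlanarPoint(0, 0), a=1.05, b=1.0, orientation=13.0)
        assert bm.long_axis_tilt(fit) is None

    def test_gate_is_strict(self):
        at_gate = bm.EllipseFit(PlanarPoint(0, 0), a=1.1, b=1.0, orientation=13.0)
        above = bm.EllipseFit(PlanarPoint(0, 0), a=1.101, b=1.0, orientation=-13.0)
        assert bm.long_axis_tilt(at_gate) is None
        assert bm.long_axis_tilt(above) == 13.0


class TestComputeBlebMetrics:
    def _record(self, outline, ret, vs_y, site="inferior"):
        return bm.EyeRecord(
            eye_id="e1", animal_id="a1", laterality="left",
            injection_site=site, injectate="aav",
            outline=outline, retinotomy=ret, vs_reference_y=vs_y,
        )

    def test_worked_example_symmetric_horizontal_bleb(self):
        rec = self._record(make_ellipse_polygon(2, 1), PlanarPoint(0, 0), 5.0)
        m = bm.compute_bleb_metrics(rec)
        assert m.a_v == 1.0
        assert m.propagation_class == "balanced"
        assert m.tilt == pytest.approx(0.0, abs=1e-9)
        assert m.eccentricity == pytest.approx(2.0, rel=0.01)
        # label says inferior but retinotomy is below VS: consistent, no warning
        assert m.warnings == []

    def test_one_sided_bleb_undefined(self):
        outline = BlebOutline([(0, 1), (2, 1), (2, 3), (0, 3)])
        rec = self._record(outline, PlanarPoint(1, 0), 10.0)
        m = bm.compute_bleb_metrics(rec)
        assert m.a_v is None and m.propagation_class == "undefined"
        assert any("undefined" in w for w in m.warnings)
        assert any("outside" in w for w in m.warnings)

    def test_label_geometry_mismatch_warns(self):
        rec = self._record(
            make_ellipse_polygon(2, 1), PlanarPoint(0, 0), 5.0, site="superior"
        )
        m = bm.compute_bleb_metrics(rec)
        assert any("inconsistent" in w for w in m.warnings)


# --- invariants -------------------------------------------------------------

def _metrics_for(outline, ret, vs_y):
    rec = bm.EyeRecord(
        eye_id="p", animal_id="p", laterality="left",
        injection_site="inferior" if vs_y > ret.y else "superior",
        injectate="aav", outline=outline, retinotomy=ret, vs_reference_y=vs_y,
    )
    return bm.compute_bleb_metrics(rec)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    dx=st.floats(-50, 50),
    dy=st.floats(-50, 50),
)
def test_translation_invariance(seed, dx, dy):
    """Shifting all geometry by a constant vector changes no metric."""
    rng = np.random.default_rng(seed)
    poly = star_polygon(rng)
    ret = PlanarPoint(0.2, float(rng.uniform(-0.5, 0.5)))
    m0 = _metrics_for(poly, ret, 8.0)
    shifted = BlebOutline(poly.vertices + [dx, dy])
    m1 = _metrics_for(shifted, PlanarPoint(ret.x + dx, ret.y + dy), 8.0 + dy)
    assert m1.a_v == pytest.approx(m0.a_v, rel=1e-9)
    assert m1.p_prox == pytest.approx(m0.p_prox, rel=1e-9, abs=1e-9)
    assert m1.area_anisotropy == pytest.approx(m0.area_anisotropy, rel=1e-6)
    assert m1.eccentricity == pytest.approx(m0.eccentricity, rel=1e-6)
    assert (m1.tilt is None) == (m0.tilt is None)
    if m0.tilt is not None:
        assert m1.tilt == pytest.approx(m0.tilt, abs=1e-6)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1), k=st.floats(0.1, 10.0))
def test_scale_invariances(seed, k):
    """Horizontal scaling leaves vertical metrics alone; isotropic scaling
    leaves all dimensionless metrics alone."""
    rng = np.random.default_rng(seed)
    poly = star_polygon(rng)
    ret = PlanarPoint(0.0, float(rng.uniform(-0.5, 0.5)))
    m0 = _metrics_for(poly, ret, 8.0)

    hor = BlebOutline(poly.vertices * [k, 1.0])
    mh = _metrics_for(hor, PlanarPoint(0.0, ret.y), 8.0)
    assert mh.p_prox == m0.p_prox and mh.p_dist == m0.p_dist
    assert mh.a_v == m0.a_v
    assert mh.area_prox == pytest.approx(k * m0.area_prox, rel=1e-9)
    assert mh.area_anisotropy == pytest.approx(m0.area_anisotropy, rel=1e-9)

    iso = BlebOutline(poly.vertices * k)
    mi = _metrics_for(iso, PlanarPoint(0.0, ret.y * k), 8.0 * k)
    assert mi.a_v == pytest.approx(m0.a_v, rel=1e-9)
    assert mi.area_anisotropy == pytest.approx(m0.area_anisotropy, rel=1e-6)
    assert mi.eccentricity == pytest.approx(m0.eccentricity, rel=1e-6)
    if m0.tilt is not None:
        assert mi.tilt == pytest.approx(m0.tilt, abs=1e-6)


@settings(max_examples=20, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**31 - 1))
def test_reflection_duality(seed):
    """Reflecting across the retinotomy's horizontal line swaps proximal and
    distal, mapping a_v to 1/a_v."""
    rng = np.random.default_rng(seed)
    poly = star_polygon(rng)
    ret = PlanarPoint(0.0, float(rng.uniform(-0.5, 0.5)))
    m0 = _metrics_for(poly, ret, 8.0)
    reflected = poly.vertices.copy()
    reflected[:, 1] = 2 * ret.y - reflected[:, 1]
    m1 = _metrics_for(BlebOutline(reflected[::-1]), ret, 8.0)
    assert m1.p_prox == pytest.approx(m0.p_dist, rel=1e-12)
    assert m1.p_dist == pytest.approx(m0.p_prox, rel=1e-12)
    assert m1.area_prox == pytest.approx(m0.area_dist, rel=1e-9)
    if m0.a_v not in (None, 0.0):
        assert m1.a_v == pytest.approx(1.0 / m0.a_v, rel=1e-9)


class TestOutlineIO:
    def test_csv_round_trip(self, tmp_path, rng):
        poly = star_polygon(rng)
        path = bm.write_outline(poly, tmp_path / "o.csv")
        back = bm.read_outline(path)
        assert np.allclose(back.vertices, poly.vertices, rtol=1e-11, atol=0)
        # a second write of the read-back outline is byte-identical
        path2 = bm.write_outline(back, tmp_path / "o2.csv")
        assert path.read_bytes() == path2.read_bytes()

    def test_geojson_round_trip(self, tmp_path, rng):
        poly = star_polygon(rng)
        path = bm.write_outline(poly, tmp_path / "o.geojson")
        back = bm.read_outline(path)
        assert np.allclose(back.vertices, poly.vertices, rtol=1e-11)

    def test_geojson_holes_rejected(self, tmp_path):
        import json

        obj = {
            "type": "Polygon",
            "coordinates": [
                [[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]],
                [[1, 1], [2, 1], [2, 2], [1, 2], [1, 1]],
            ],
        }
        p = tmp_path / "holes.geojson"
        p.write_text(json.dumps(obj))
        with pytest.raises(ValidationError):
            bm.read_outline(p)

    def test_csv_bad_header_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1,2\n3,4\n5,6\n")
        with pytest.raises(ValidationError):
            bm.read_outline(p)
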