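import numpy as np
import pytest
from hypothesis import given, strategies as st

from dtspos.geometry import (
    ScanGeometry,
    circular_distance_deg,
    load_geometry_config,
    make_full_fan_geometry,
    projection_savings,
    select_arc,
    source_and_ray,
)


class TestFullFanGeometry:
    def test_clinical_protocol_spacing(self):
        geom = make_full_fan_geometry(20.0, 200.0, 375)
        assert geom.angular_spacing_deg == pytest.approx(200.0 / 375)
        assert round(geom.angular_spacing_deg, 2) == 0.53
        assert geom.n_angles == 375

    def test_single_view_degenerate(self):
        geom = make_full_fan_geometry(0.0, 1.0, 1)
        assert geom.n_angles == 1
        assert geom.angles_deg[0] == 0.0
        assert geom.angular_spacing_deg == 1.0

    def test_ninety_views_closed_form(self):
        geom = make_full_fan_geometry(0.0, 90.0, 90)
        assert geom.angular_spacing_deg == pytest.approx(1.0)
        assert geom.angles_deg[-1] == pytest.approx(-89.0)
        cw = make_full_fan_geometry(0.0, 90.0, 90, direction="cw")
        assert cw.angles_deg[-1] == pytest.approx(89.0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_full_fan_geometry(0.0, -10.0, 5)
        with pytest.raises(ValueError):
            make_full_fan_geometry(0.0, 10.0, 0)

    def test_angles_monotone_and_wrapped_reporting(self):
        geom = make_full_fan_geometry(20.0, 200.0, 375)
        assert np.all(np.diff(geom.angles_deg) < 0)
        wrapped = geom.angles_wrapped_deg()
        assert np.all((wrapped >= 0) & (wrapped < 360))


@pytest.fixture(scope="module")
def full():
    return make_full_fan_geometry(20.0, 200.0, 375)


class TestSelectArc:

    def test_count_matches_brute_force(self, full):
        # independent enumeration of angles within +/-20 deg of 0
        expected = sum(
            1 for a in full.angles_deg if abs((a + 180.0) % 360.0 - 180.0) <= 20.0
        )
        arc = select_arc(full, 0.0, 40.0)
        assert arc.n_angles == expected

    def test_twenty_degree_arc_count(self, full):
        # the clinical report rounds this count to 37; the exact
        # circular-distance rule on the 20-to--180 protocol yields 38
        arc = select_arc(full, 0.0, 20.0)
        assert arc.n_angles == 38

    def test_window_superset(self, full):
        arc = select_arc(full, 0.0, 720.0)
        assert arc.n_angles == full.n_angles

    def test_wraparound_window(self, full):
        # 270 deg center must catch the -90 deg region of the scan
        arc = select_arc(full, 270.0, 40.0)
        assert arc.n_angles > 0
        assert np.all(circular_distance_deg(arc.angles_deg, 270.0) <= 20.0 + 1e-9)

    def test_idempotent(self, full):
        once = select_arc(full, 0.0, 40.0)
        twice = select_arc(once, 0.0, 40.0)
        np.testing.assert_array_equal(once.angles_deg, twice.angles_deg)

    def test_empty_selection_errors(self, full):
        with pytest.raises(ValueError, match="window"):
            select_arc(full, 120.0, 1.0)


class TestProjectionSavings:
    def test_paper_protocol(self):
        assert projection_savings(75, 375) == pytest.approx(80.0)

    def test_trivial_bounds(self):
        assert projection_savings(375, 375) == 0.0
        assert projection_savings(0, 375) == 100.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            projection_savings(400, 375)
        with pytest.raises(ValueError):
            projection_savings(1, 0)

    @given(
        n_full=st.integers(min_value=1, max_value=10000),
        frac=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_range_property(self, n_full, frac):
        n_dts = int(frac * n_full)
        s = projection_savings(n_dts, n_full)
        assert 0.0 <= s <= 100.0


class TestRays:
    def test_central_ray_at_zero_deg(self, tiny_geom):
        center = (tiny_geom.detector_nu // 2, tiny_geom.detector_nv // 2)
        origin, direction = source_and_ray(tiny_geom, 0.0, center)
        np.testing.assert_allclose(direction, [0.0, 0.0, -1.0], atol=1e-12)
        np.testing.assert_allclose(origin, [0.0, 0.0, tiny_geom.sad_mm], atol=1e-9)

    def test_lateral_ray_at_270(self, tiny_geom):
        center = (tiny_geom.detector_nu // 2, tiny_geom.detector_nv // 2)
        _, direction = source_and_ray(tiny_geom, 270.0, center)
        np.testing.assert_allclose(np.abs(direction), [1.0, 0.0, 0.0], atol=1e-12)

    def test_corner_ray_unit_norm_and_colinear(self, tiny_geom):
        from dtspos.geometry import detector_pixel_position

        origin, direction = source_and_ray(tiny_geom, 33.0, (0, 0))
        assert np.linalg.norm(direction) == pytest.approx(1.0)
        target = detector_pixel_position(tiny_geom, 33.0, 0, 0)
        cross = np.cross(direction, target - origin)
        assert np.linalg.norm(cross) == pytest.approx(0.0, abs=1e-9)

    def test_periodicity_and_antiparallel(self, tiny_geom):
        center = (tiny_geom.detector_nu // 2, tiny_geom.detector_nv // 2)
        o1, d1 = source_and_ray(tiny_geom, 40.0, center)
        o2, d2 = source_and_ray(tiny_geom, 400.0, center)
        np.testing.assert_allclose(o1, o2, atol=1e-9)
        np.testing.assert_allclose(d1, d2, atol=1e-12)
        _, d3 = source_and_ray(tiny_geom, 220.0, center)
        np.testing.assert_allclose(d3, -d1, atol=1e-12)

    def test_out_of_grid_pixel(self, tiny_geom):
        with pytest.raises(IndexError):
            source_and_ray(tiny_geom, 0.0, (tiny_geom.detector_nu, 0))


class TestGeometryValidation:
    def test_sad_sdd_ordering(self):
        with pytest.raises(ValueError):
            ScanGeometry(1500.0, 1000.0, 8, 8, 1.0, np.array([0.0]), 1.0)

    def test_non_monotone_angles(self):
        with pytest.raises(ValueError):
            ScanGeometry(1000.0, 1500.0, 8, 8, 1.0, np.array([0.0, 5.0, 3.0]), 1.0)


def test_config_roundtrip(tmp_path):
    cfg = """
sad_mm: 1000
sdd_mm: 1500
detector: {nu: 64, nv: 48, pixel_mm: 1.552}
scan: {start_deg: 20, range_deg: 200, n_projections: 375}
arcs:
  - {center_deg: 0, arc_deg: 40}
  - {center_deg: 270, arc_deg: 40}
"""
    p = tmp_path / "geom.yaml"
    p.write_text(cfg)
    out = load_geometry_config(p)
    geom = out["geometry"]
    assert geom.detector_nu == 64
    assert geom.n_angles == 375
    assert len(out["arcs"]) == 2
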