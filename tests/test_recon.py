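import numpy as np
import pytest

from dtspos.drr import ProjectionImage, ProjectionSet, drr_fast, to_intensity
from dtspos.metrics import correlation_coefficient
from dtspos.phantoms import VoxelVolume
from dtspos.recon import (
    BlendSpec,
    DTSVolumeSpec,
    FilterSpec,
    preprocess_projection,
    reconstruct_dts,
    stitch_halffan,
)


@pytest.fixture(scope="module")
def cube_arc_set(small_cube, tiny_arc):
    return drr_fast(small_cube, tiny_arc)


@pytest.fixture(scope="module")
def dts_spec_small():
    return DTSVolumeSpec(
        orientation="coronal", pixel_mm=1.0, slice_thickness_mm=2.0,
        n_slices=8, n_inplane=(80, 80),
    )


class TestPreprocess:
    def test_flood_image_filters_to_zero(self, tiny_geom):
        pixels = np.ones((tiny_geom.detector_nu, tiny_geom.detector_nv))
        p = ProjectionImage(pixels, 0.0, "intensity", tiny_geom)
        out = preprocess_projection(p, I0=1.0)
        assert np.abs(out.pixels).max() <= 1e-12

    def test_constant_row_dc_killed_exactly(self):
        from dtspos.recon import ramp_filter_rows

        q = np.full((65, 49), 3.7)
        assert np.abs(ramp_filter_rows(q, 1.0)).max() <= 1e-6 * 3.7

    def test_constant_log_image_near_zero(self, tiny_geom):
        pixels = np.full((tiny_geom.detector_nu, tiny_geom.detector_nv), 3.7)
        p = ProjectionImage(pixels, 0.0, "line_integral", tiny_geom)
        out = preprocess_projection(p)
        # the cosine pre-weight turns the constant image into a slowly
        # varying one; only that leakage survives the ramp filter
        assert np.abs(out.pixels).max() <= 0.02 * 3.7

    def test_linearity(self, cube_arc_set):
        p = cube_arc_set[0]
        one = preprocess_projection(p)
        scaled = preprocess_projection(
            ProjectionImage(3.0 * p.pixels, p.angle_deg, p.domain, p.geometry)
        )
        np.testing.assert_allclose(scaled.pixels, 3.0 * one.pixels, atol=1e-12)

    def test_nonpositive_intensity_rejected(self, tiny_geom):
        pixels = np.ones((tiny_geom.detector_nu, tiny_geom.detector_nv))
        pixels[3, 4] = 0.0
        p = ProjectionImage(pixels, 0.0, "intensity", tiny_geom)
        with pytest.raises(ValueError, match="1 non-positive"):
            preprocess_projection(p)


class TestReconstruct:
    def test_zero_projections_zero_volume(self, tiny_arc, dts_spec_small):
        zeros = tuple(
            ProjectionImage(
                np.zeros((tiny_arc.detector_nu, tiny_arc.detector_nv)),
                float(a), "line_integral", tiny_arc,
            )
            for a in tiny_arc.angles_deg
        )
        vol = reconstruct_dts(ProjectionSet(tiny_arc, zeros), dts_spec_small)
        assert np.all(vol.values == 0)

    def test_empty_set_rejected(self, dts_spec_small, tiny_arc):
        with pytest.raises(ValueError):
            reconstruct_dts(
                ProjectionSet(tiny_arc, ()), dts_spec_small
            )

    def test_linearity(self, cube_arc_set, dts_spec_small):
        doubled = ProjectionSet(
            cube_arc_set.geometry,
            tuple(
                ProjectionImage(2.0 * p.pixels, p.angle_deg, p.domain, p.geometry)
                for p in cube_arc_set.images
            ),
        )
        v1 = reconstruct_dts(cube_arc_set, dts_spec_small)
        v2 = reconstruct_dts(doubled, dts_spec_small)
        scale = np.abs(v1.values).max()
        assert np.abs(v2.values - 2.0 * v1.values).max() <= 1e-6 * scale

    def test_engines_agree(self, cube_arc_set, dts_spec_small):
        fast = reconstruct_dts(cube_arc_set, dts_spec_small, engine="fast")
        oracle = reconstruct_dts(cube_arc_set, dts_spec_small, engine="oracle")
        scale = np.abs(oracle.values).max()
        assert np.abs(fast.values - oracle.values).max() <= 1e-3 * scale
        assert correlation_coefficient(fast.values, oracle.values) >= 0.99

    def test_orientation_layout(self, cube_arc_set):
        spec = DTSVolumeSpec(
            orientation="coronal", pixel_mm=1.0, slice_thickness_mm=2.0,
            n_slices=4, n_inplane=(60, 50),
        )
        vol = reconstruct_dts(cube_arc_set, spec)
        assert vol.shape == (60, 50, 4)
        assert vol.voxel_mm == (1.0, 1.0, 2.0)
        assert vol.orientation == "coronal"

    def test_in_plane_centroid_accuracy(self, cube_arc_set, dts_spec_small):
        # coronal stack from a 0-deg arc localizes LAT/LNG to sub-voxel
        vol = reconstruct_dts(cube_arc_set, dts_spec_small)
        v = np.clip(vol.values, 0.0, None)
        for ax in (0, 1):
            proj = v.sum(axis=tuple(a for a in range(3) if a != ax))
            centers = vol.axis_centers_mm(ax)
            centroid = float((proj * centers).sum() / proj.sum())
            assert abs(centroid) <= 0.5

    def test_onboard_route_matches_reference_route(self, cube_arc_set, dts_spec_small):
        # log conversion of intensities must reproduce the line-integral path
        onboard = ProjectionSet(
            cube_arc_set.geometry,
            tuple(to_intensity(p, 1.0) for p in cube_arc_set.images),
        )
        v_ref = reconstruct_dts(cube_arc_set, dts_spec_small)
        v_ob = reconstruct_dts(onboard, dts_spec_small)
        np.testing.assert_allclose(v_ob.values, v_ref.values, atol=1e-9)

    def test_off_center_arc_warns(self, cube_arc_set, dts_spec_small, caplog):
        import logging

        spec = DTSVolumeSpec(
            orientation="sagittal", pixel_mm=1.0, slice_thickness_mm=2.0,
            n_slices=4, n_inplane=(60, 50),
        )
        with caplog.at_level(logging.WARNING, logger="dtspos.recon"):
            reconstruct_dts(cube_arc_set, spec)
        assert any("expected near 270" in m for m in caplog.messages)


class TestStitchHalffan:
    @pytest.fixture()
    def stack(self, cube_arc_set, dts_spec_small):
        return reconstruct_dts(cube_arc_set, dts_spec_small)

    def test_identical_inputs_identity(self, stack):
        out = stitch_halffan(stack, stack, BlendSpec(band_mm=20.0))
        np.testing.assert_allclose(out.values, stack.values, atol=1e-12)

    def test_zero_overlap_exact_union(self, stack):
        left = VoxelVolume(
            np.where(stack.axis_centers_mm(0)[:, None, None] < 0, stack.values, 0.0),
            stack.voxel_mm, stack.origin_mm, orientation=stack.orientation,
        )
        right = VoxelVolume(
            np.where(stack.axis_centers_mm(0)[:, None, None] >= 0, stack.values, 0.0),
            stack.voxel_mm, stack.origin_mm, orientation=stack.orientation,
        )
        out = stitch_halffan(left, right, BlendSpec(axis=0, boundary_mm=0.0, band_mm=0.0))
        np.testing.assert_allclose(out.values, stack.values, atol=1e-12)

    def test_midline_cross_fade_mean(self, stack):
        other = VoxelVolume(
            stack.values + 1.0, stack.voxel_mm, stack.origin_mm,
            orientation=stack.orientation,
        )
        out = stitch_halffan(stack, other, BlendSpec(axis=0, boundary_mm=0.0, band_mm=40.0))
        centers = stack.axis_centers_mm(0)
        mid = int(np.argmin(np.abs(centers)))
        expected_w = np.clip((0.0 + 20.0 - centers[mid]) / 40.0, 0, 1)
        expected = expected_w * stack.values[mid] + (1 - expected_w) * other.values[mid]
        np.testing.assert_allclose(out.values[mid], expected, atol=1e-12)

    def test_grid_mismatch_rejected(self, stack):
        other = VoxelVolume(
            stack.values[:-1], stack.voxel_mm, stack.origin_mm,
            orientation=stack.orientation,
        )
        with pytest.raises(ValueError):
            stitch_halffan(stack, other)


class TestSpecValidation:
    def test_bad_orientation(self):
        with pytest.raises(ValueError):
            DTSVolumeSpec(orientation="axial")

    def test_bad_sizes(self):
        with pytest.raises(ValueError):
            DTSVolumeSpec(pixel_mm=0.0)
        with pytest.raises(ValueError):
            DTSVolumeSpec(n_slices=0)
        with pytest.raises(ValueError):
            FilterSpec(window="hann")

    def test_sagittal_layout(self):
        spec = DTSVolumeSpec(
            orientation="sagittal", pixel_mm=0.5, slice_thickness_mm=1.5,
            n_slices=16, n_inplane=(100, 90),
        )
        shape, voxel = spec.grid()
        assert shape == (16, 100, 90)
        assert voxel == (1.5, 0.5, 0.5)
        assert spec.slice_axis == 0
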