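"""Cylindrical conversion, segmentation and layer extraction."""

import numpy as np
import pytest

from spindry.phantom import Defect, PhantomSpec, make_annulus_frame, \
    uniform_thickness
from spindry.tomo import (
    CylindricalFrame,
    LayerSeries,
    ScanGeometry,
    VolumeFrame,
    cylindrical_volume,
    estimate_axis,
    extract_layer_series,
    extract_radii,
    integrated_length,
    radiality_map,
    segment_ice,
    to_cylindrical,
)

from conftest import make_geometry


def render_solid_cylinder(geometry, radius, center=None, level=1.0):
    """Partial-volume-free binary cylinder for conversion tests."""
    cx, cy = center or (geometry.n_x / 2.0, geometry.n_y / 2.0)
    x = (np.arange(geometry.n_x) + 0.5 - cx) * geometry.voxel_size
    y = (np.arange(geometry.n_y) + 0.5 - cy) * geometry.voxel_size
    rr = np.hypot(*np.meshgrid(x, y))
    img = (rr < radius).astype(np.float32) * level
    return VolumeFrame(0.0, np.repeat(img[None], geometry.n_z, axis=0))


class TestScanGeometry:
    def test_valid_roundtrip(self, small_geom):
        assert ScanGeometry.from_dict(small_geom.to_dict()) == small_geom

    def test_rejects_nonpositive_voxel(self):
        with pytest.raises(ValueError):
            make_geometry(voxel=-1e-5)

    def test_rejects_uncovered_r_vial(self):
        with pytest.raises(ValueError, match="r_vial"):
            ScanGeometry(voxel_size=1e-4, n_x=64, n_y=64, n_z=8,
                         n_radial=10, n_azimuth=8, n_height=4,
                         r_vial=10.9e-3, h_vial=8e-4)

    def test_grid_centers(self, small_geom):
        g = small_geom
        assert g.r_centers[0] == pytest.approx(g.dr / 2)
        assert g.phi_centers[0] == pytest.approx(np.pi / g.n_azimuth)
        assert len(g.h_centers) == g.n_height


class TestToCylindrical:
    def test_solid_cylinder_occupancy(self, small_geom):
        g = small_geom
        radius = 6.0e-3
        frame = render_solid_cylinder(g, radius)
        cyl = to_cylindrical(frame, g, (g.n_x / 2, g.n_y / 2))
        r = g.r_centers
        inside = r < radius - g.voxel_size
        outside = r > radius + g.voxel_size
        assert np.all(cyl.values[inside] > 0.99)
        assert np.all(cyl.values[outside][cyl.valid[outside]] < 0.01)

    def test_volume_conserved_within_2pct(self, small_geom):
        g = small_geom
        spec = PhantomSpec(seed=0, initial_thickness=uniform_thickness(g, 2e-3),
                           attenuation={"air": 0.0, "ice": 1.0, "glass": 0.0})
        frame = make_annulus_frame(spec, g)
        cart = float(frame.data.sum()) * g.voxel_size ** 3
        cyl = to_cylindrical(frame, g, (g.n_x / 2, g.n_y / 2))
        assert cylindrical_volume(cyl.values, g) == pytest.approx(
            cart, rel=0.02)

    def test_off_center_with_correct_axis(self, small_geom):
        g = small_geom
        t_true = 2.0e-3
        spec = PhantomSpec(seed=0, initial_thickness=uniform_thickness(g, t_true))
        center = (g.n_x / 2 + 5, g.n_y / 2)
        frame = make_annulus_frame(spec, g, axis_center=center)
        cyl = to_cylindrical(frame, g, center)
        mask = segment_ice(cyl, g)
        _, l_ice = extract_radii(mask, g, values=cyl.values)
        assert np.max(np.abs(l_ice - t_true)) <= g.voxel_size

    def test_axis_outside_rejected(self, small_geom):
        frame = render_solid_cylinder(small_geom, 5e-3)
        with pytest.raises(ValueError, match="axis"):
            to_cylindrical(frame, small_geom, (-10.0, 5.0))


class TestEstimateAxis:
    def test_centered_within_half_voxel(self, static_phantom):
        _, geom, _, frame = static_phantom
        cx, cy = estimate_axis(frame)
        assert abs(cx - geom.n_x / 2) <= 0.5
        assert abs(cy - geom.n_y / 2) <= 0.5

    def test_offset_phantom_within_one_voxel(self, small_geom):
        g = small_geom
        spec = PhantomSpec(seed=0, initial_thickness=uniform_thickness(g, 2e-3))
        true_center = (g.n_x / 2 + 5, g.n_y / 2 - 3)
        frame = make_annulus_frame(spec, g, axis_center=true_center)
        cx, cy = estimate_axis(frame)
        assert abs(cx - true_center[0]) <= 1.0
        assert abs(cy - true_center[1]) <= 1.0

    def test_zero_volume_rejected(self, small_geom):
        g = small_geom
        frame = VolumeFrame(0.0, np.zeros((g.n_z, g.n_y, g.n_x)))
        with pytest.raises(ValueError, match="no annulus"):
            estimate_axis(frame)


def truth_occupancy(geometry, thickness):
    """Analytic cylindrical-grid ice occupancy of a defect-free annulus."""
    r = geometry.r_centers[:, None, None]
    r_in = geometry.r_vial - thickness[None, :, :]
    return (r >= r_in) & (r < geometry.r_vial)


class TestSegmentIce:
    def test_noise_free_matches_rendered_region(self, static_phantom):
        _, geom, thickness, frame = static_phantom
        cyl = to_cylindrical(frame, geom, (geom.n_x / 2, geom.n_y / 2))
        mask = segment_ice(cyl, geom)
        truth = truth_occupancy(geom, thickness)
        # interior bins: more than one voxel away from either interface
        r = geom.r_centers[:, None, None]
        r_in = geom.r_vial - thickness[None, :, :]
        interior = ((r > r_in + geom.dr) & (r < geom.r_vial - geom.dr)) | \
                   (r < r_in - geom.dr)
        assert np.array_equal(mask[interior], truth[interior])

    def test_noisy_errors_confined_to_interface_shell(self, small_geom):
        g = small_geom
        t = uniform_thickness(g, 2e-3)
        clean = PhantomSpec(seed=7, initial_thickness=t)
        noisy = PhantomSpec(seed=7, initial_thickness=t, noise_sd=0.05)
        center = (g.n_x / 2, g.n_y / 2)
        m_clean = segment_ice(
            to_cylindrical(make_annulus_frame(clean, g), g, center), g)
        m_noisy = segment_ice(
            to_cylindrical(make_annulus_frame(noisy, g), g, center), g)
        diff = m_clean ^ m_noisy
        r = g.r_centers[:, None, None]
        r_in = g.r_vial - t[None, :, :]
        shell = (np.abs(r - r_in) <= g.dr) | \
            (np.abs(r - g.r_vial) <= 2 * g.dr)
        assert not np.any(diff & ~np.broadcast_to(shell, diff.shape))

    def test_fixed_threshold_above_ice_gives_empty_mask(self, static_phantom):
        _, geom, _, frame = static_phantom
        cyl = to_cylindrical(frame, geom, (geom.n_x / 2, geom.n_y / 2))
        mask = segment_ice(cyl, geom, threshold=10.0)
        assert not mask.any()

    def test_degenerate_histogram_rejected(self, small_geom):
        g = small_geom
        shape = (g.n_radial, g.n_azimuth, g.n_height)
        cyl = CylindricalFrame(0.0, np.zeros(shape), np.ones(shape, bool))
        with pytest.raises(ValueError, match="degenerate"):
            segment_ice(cyl, g)

    def test_idempotent_on_binary_frame(self, small_geom):
        g = small_geom
        truth = truth_occupancy(g, uniform_thickness(g, 2e-3))
        cyl = CylindricalFrame(0.0, truth.astype(float),
                               np.ones_like(truth, bool))
        assert np.array_equal(segment_ice(cyl, g), truth)


class TestExtractRadii:
    def test_uniform_annulus(self, small_geom):
        g = small_geom
        mask = truth_occupancy(g, uniform_thickness(g, 2e-3))
        r_p, l_ice = extract_radii(mask, g)
        assert np.allclose(l_ice, 2e-3, atol=g.dr / 2)
        assert np.allclose(r_p, g.r_vial - 2e-3, atol=g.dr / 2)

    def test_empty_column(self, small_geom):
        g = small_geom
        mask = np.zeros((g.n_radial, g.n_azimuth, g.n_height), bool)
        r_p, l_ice = extract_radii(mask, g)
        assert np.all(l_ice == 0)
        assert np.all(r_p == g.r_vial)

    def test_eccentric_annulus_sinusoidal(self, small_geom):
        from spindry.phantom import graded_thickness

        g = small_geom
        t = graded_thickness(g, 2e-3, eccentricity=0.1)   # +-0.2 mm
        spec = PhantomSpec(seed=0, initial_thickness=t)
        frame = make_annulus_frame(spec, g)
        cyl = to_cylindrical(frame, g, (g.n_x / 2, g.n_y / 2))
        mask = segment_ice(cyl, g)
        _, l_ice = extract_radii(mask, g, values=cyl.values)
        assert np.max(np.abs(l_ice - t)) <= g.voxel_size
        amp = (l_ice.max(axis=0) - l_ice.min(axis=0)) / 2
        assert np.allclose(amp, 0.1 * 2e-3, atol=g.voxel_size)

    def test_mask_shape_checked(self, small_geom):
        with pytest.raises(ValueError, match="dims"):
            extract_radii(np.zeros((3, 3, 3), bool), small_geom)


class TestIntegratedLength:
    def test_contiguous_bins(self, small_geom):
        g = small_geom
        mask = np.zeros((g.n_radial, g.n_azimuth, g.n_height), bool)
        mask[10:60, 0, 0] = True        # 50 bins of 100 um
        lp = integrated_length(mask, g)
        assert lp[0, 0] == pytest.approx(50 * g.dr)
        assert lp[1, 0] == 0.0

    def test_cavity_reduces_integrated_length(self, small_geom):
        g = small_geom
        # thickness 2.1 mm centres the cavity on a radial bin center, so
        # the 0.3 mm void spans exactly three whole bins
        t = uniform_thickness(g, 2.1e-3)
        patch_phi, patch_h = (0.5, 1.5), (0.0, g.h_vial)
        spec = PhantomSpec(
            seed=0, initial_thickness=t,
            defects=[Defect("cavity", patch_phi, patch_h,
                            radial_extent=3.0e-4)])
        frame = make_annulus_frame(spec, g)
        cyl = to_cylindrical(frame, g, (g.n_x / 2, g.n_y / 2))
        mask = segment_ice(cyl, g)
        _, l_ice = extract_radii(mask, g, values=cyl.values)
        lp = integrated_length(mask, g)
        in_patch = (g.phi_centers >= 0.5) & (g.phi_centers < 1.5)
        assert np.allclose((l_ice - lp)[in_patch], 3.0e-4,
                           atol=g.voxel_size)
        assert np.allclose((l_ice - lp)[~in_patch], 0.0, atol=g.voxel_size)


class TestRadialityMap:
    def test_fully_radial(self):
        l = np.full((4, 3), 2e-3)
        res = radiality_map(l, l.copy())
        assert not res.non_radial
        assert np.allclose(res.rel_diff, 0.0)

    def test_arithmetic(self):
        res = radiality_map(np.array([[2.0e-3]]), np.array([[1.7e-3]]))
        assert res.rel_diff[0, 0] == pytest.approx(0.15)
        assert res.non_radial

    def test_zero_thickness_undefined(self):
        l = np.array([[0.0, 2e-3]])
        lp = np.array([[0.0, 2e-3]])
        res = radiality_map(l, lp)
        assert not res.defined[0, 0]
        assert np.isnan(res.rel_diff[0, 0])
        assert not res.non_radial


class TestLayerSeries:
    def test_invariants_enforced(self):
        times = np.arange(3.0)
        ok = np.full((3, 2, 2), 1e-3)
        LayerSeries(times, ok, ok * 0.9, 10.9e-3 - ok, 10.9e-3)
        with pytest.raises(ValueError, match="L_ice'"):
            LayerSeries(times, ok, ok * 1.1, 10.9e-3 - ok, 10.9e-3)
        with pytest.raises(ValueError, match="increasing"):
            LayerSeries(np.zeros(3), ok, ok, 10.9e-3 - ok, 10.9e-3)

    def test_extract_series_invariants(self, forward_clean):
        s = forward_clean.series
        assert np.all(s.l_ice_prime <= s.l_ice + 1e-12)
        assert np.all(s.l_ice <= np.asarray(s.r_vial) + 1e-12)
        assert np.all(s.l_ice_prime >= 0)

    def test_geometry_recovery_noise_free(self, static_phantom):
        spec, geom, thickness, frame = static_phantom
        series = extract_layer_series([frame], geom)
        assert np.max(np.abs(series.l_ice[0] - thickness)) <= geom.voxel_size
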