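"""Resistance regression: smoothing, rates, areas, profiles, binning."""

import numpy as np
import pytest

from spindry.physics import DEFAULT_CONSTANTS, vapor_pressure_ice
from spindry.resistance import (
    BIN_EDGES,
    ProcessTrace,
    RpProfileField,
    bin_profiles,
    dried_thickness,
    pool_coordinates,
    projected_area,
    resistance_profile,
    segment_volume,
    smooth_thickness,
    sublimation_rate,
)
from spindry.tomo import LayerSeries

from conftest import make_geometry, shape_for_azimuth


def make_series(l_ice, times=None, r_vial=10.9e-3):
    """LayerSeries from a (T, n, m) thickness array, radial by default."""
    l_ice = np.asarray(l_ice, dtype=float)
    if times is None:
        times = np.arange(l_ice.shape[0], dtype=float) * 60.0
    return LayerSeries(times=times, l_ice=l_ice, l_ice_prime=l_ice.copy(),
                       r_p=r_vial - l_ice, r_vial=r_vial)


def sg_reference(y, window=15, order=3):
    """Independent SG smoother: per-point LSQ polynomial fit on windows."""
    n = len(y)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        idx = np.arange(lo, lo + window)
        coeffs = np.polyfit(idx - i, y[idx], order)
        out[i] = coeffs[-1]
    return out


class TestSmoothThickness:
    def test_cubic_polynomial_is_reproduced(self):
        t = np.arange(20, dtype=float)
        cubic = 1e-3 + 1e-5 * t - 3e-7 * t ** 2 + 2e-9 * t ** 3
        series = make_series(np.tile(cubic[:, None, None], (1, 2, 2)),
                             times=t * 60.0)
        out = smooth_thickness(series)
        assert np.allclose(out.l_ice, series.l_ice, rtol=1e-12, atol=1e-18)

    def test_matches_independent_windowed_fit(self):
        rng = np.random.default_rng(0)
        ramp = np.linspace(2e-3, 1e-3, 40)
        noisy = ramp + rng.normal(0, 2e-5, 40)
        series = make_series(np.clip(noisy, 0, None)[:, None, None])
        out = smooth_thickness(series).l_ice[:, 0, 0]
        ref = sg_reference(noisy)
        assert np.allclose(out, np.clip(ref, 0, None), atol=1e-12)

    def test_noise_reduction_factor(self):
        rng = np.random.default_rng(1)
        sigma = 2e-5
        ramp = np.linspace(2e-3, 1e-3, 200)
        noisy = ramp + rng.normal(0, sigma, 200)
        series = make_series(noisy[:, None, None])
        out = smooth_thickness(series).l_ice[:, 0, 0]
        resid = out[10:-10] - ramp[10:-10]
        assert resid.std() <= 0.5 * sigma

    def test_short_series_rejected(self):
        series = make_series(np.full((10, 2, 2), 1e-3))
        with pytest.raises(ValueError, match="15"):
            smooth_thickness(series)


class TestSegmentVolume:
    geom = make_geometry(n_azimuth=16, n_height=8)

    def test_zero_at_wall(self):
        assert segment_volume(self.geom.r_vial, self.geom) == 0.0

    def test_hand_value(self):
        # pi * 0.032 / 1.6e6 * (0.0109^2 - 0.0089^2) = 2.488e-12 m^3
        g = make_geometry(n_azimuth=1600, n_height=1000, h_vial=3.2e-3)
        object.__setattr__(g, "h_vial", 32e-3)    # full vial height
        v = segment_volume(8.9e-3, g)
        assert v == pytest.approx(2.488e-12, rel=1e-3)

    def test_halves_when_segments_double(self):
        g1 = make_geometry(n_azimuth=8, n_height=8)
        g2 = make_geometry(n_azimuth=16, n_height=8)
        assert segment_volume(8.9e-3, g1) == pytest.approx(
            2 * segment_volume(8.9e-3, g2))

    def test_rejects_rp_beyond_wall(self):
        with pytest.raises(ValueError):
            segment_volume(self.geom.r_vial + 1e-4, self.geom)


class TestSublimationRate:
    def test_hand_value(self):
        # |dV/dt| = 3.1e-16 -> mdot = 3.1e-16 * 918 * 0.97 = 2.76e-13 kg/s
        times = np.arange(20.0)
        v = (1e-11 - 3.1e-16 * times)[:, None, None]
        mdot, valid = sublimation_rate(v, times)
        assert np.all(valid)
        assert mdot[10, 0, 0] == pytest.approx(3.1e-16 * 918 * 0.97,
                                               rel=1e-6)

    def test_constant_volume_masked(self):
        v = np.full((20, 1, 1), 1e-11)
        mdot, valid = sublimation_rate(v, np.arange(20.0))
        assert not valid.any()
        assert np.all(np.isnan(mdot))

    def test_increasing_volume_masked_not_negative(self):
        v = (1e-11 + 1e-15 * np.arange(20.0))[:, None, None]
        mdot, valid = sublimation_rate(v, np.arange(20.0))
        assert not valid.any()
        assert not np.any(mdot[np.isfinite(mdot)] < 0)

    def test_nonuniform_times_rejected(self):
        v = np.ones((16, 1, 1))
        with pytest.raises(ValueError, match="uniform"):
            sublimation_rate(v, np.arange(16.0) ** 2)


class TestProjectedArea:
    geom = TestSegmentVolume.geom

    def test_hand_value(self):
        g = make_geometry(n_azimuth=1600, n_height=1000)
        object.__setattr__(g, "h_vial", 32e-3)
        # 2*pi*0.032*0.0089/1.6e6 = 1.118e-9 m^2
        assert projected_area(8.9e-3, g) == pytest.approx(1.118e-9,
                                                          rel=1e-3)

    def test_linear_in_radius(self):
        a1 = projected_area(4e-3, self.geom)
        a2 = projected_area(8e-3, self.geom)
        assert a2 == pytest.approx(2 * a1)

    def test_zero_radius(self):
        assert projected_area(0.0, self.geom) == 0.0


class TestDriedThickness:
    def test_difference(self):
        assert dried_thickness(2.0e-3, 1.5e-3) == pytest.approx(0.5e-3)

    def test_equal_inputs(self):
        assert dried_thickness(1.0e-3, 1.0e-3) == 0.0

    def test_full_drying(self):
        assert dried_thickness(2.0e-3, 0.0) == pytest.approx(2.0e-3)

    def test_clamped_at_zero(self):
        assert dried_thickness(1.0e-3, 1.2e-3) == 0.0


class TestResistanceProfile:
    def test_hand_example_arithmetic(self):
        # R_p = A_p (P_i - P_c) / mdot
        assert 1.118e-9 * 30.0 / 2.76e-13 == pytest.approx(1.215e5,
                                                           rel=1e-3)

    def test_linear_shrinkage_recovers_formula(self):
        """Constructed series with known shrink rate; oracle by hand."""
        g = make_geometry(n_azimuth=4, n_height=3)
        times = np.arange(25.0) * 60.0
        rate = 1.0e-8                   # m/s thickness loss
        l0 = 2.0e-3
        l_ice = np.tile((l0 - rate * times)[:, None, None], (1, 4, 3))
        series = make_series(l_ice, times=times, r_vial=g.r_vial)
        t_i = 251.0
        trace = ProcessTrace(times=times,
                             t_interface=np.full(times.size, t_i),
                             p_chamber=5.0)
        field = resistance_profile(series, trace, g)
        c = DEFAULT_CONSTANTS
        k = 10                          # interior time index
        r_p = g.r_vial - l_ice[k, 0, 0]
        dvdt = (np.pi * g.h_vial / g.segment_count) * 2 * r_p * (-rate)
        mdot = -dvdt * c.rho_ice * c.theta_dried
        expected = (projected_area(r_p, g)
                    * (vapor_pressure_ice(t_i) - 5.0) / mdot)
        assert field.valid[k, 0, 0]
        assert field.r_p[k, 0, 0] == pytest.approx(expected, rel=1e-6)

    def test_zero_driving_force_masked(self):
        g = make_geometry(n_azimuth=2, n_height=2)
        times = np.arange(20.0) * 60.0
        l_ice = np.tile(np.linspace(2e-3, 1e-3, 20)[:, None, None],
                        (1, 2, 2))
        series = make_series(l_ice, times=times, r_vial=g.r_vial)
        t_i = np.full(times.size, 251.0)
        p_c = float(vapor_pressure_ice(251.0))     # P_i == P_c
        trace = ProcessTrace(times=times, t_interface=t_i, p_chamber=p_c)
        with pytest.raises(ValueError, match="no valid"):
            resistance_profile(series, trace, g)

    def test_valid_entries_positive_finite(self, forward_noisy):
        field = forward_noisy.field
        vals = field.r_p[field.valid]
        assert np.all(np.isfinite(vals))
        assert np.all(vals > 0)

    def test_recovery_smoke_constant_profile(self, forward_clean):
        """Azimuths carrying the constant 1e5 m/s truth recover it."""
        binned = forward_clean.binned
        centers = binned.bin_centers
        sel_bins = (centers > 0.3e-3) & (centers < 1.5e-3)
        rel_errs = []
        for a in range(0, 16, 3):       # constant-shape azimuths
            prof = binned.rp_median[a, :, sel_bins]
            ok = np.isfinite(prof)
            rel_errs.append(np.abs(prof[ok] - 1e5) / 1e5)
        med = np.median(np.concatenate(rel_errs))
        assert med <= 0.10


class TestBinProfiles:
    def make_single_point_field(self, l_dr_value, rp_value=1e5):
        l = np.full((1, 1, 1), l_dr_value)
        r = np.full((1, 1, 1), rp_value)
        return RpProfileField(times=np.array([0.0]), l_dr=l, r_p=r,
                              valid=np.ones((1, 1, 1), bool))

    def test_point_at_1_06mm_lands_in_bin_16(self):
        field = self.make_single_point_field(1.06e-3)
        binned = bin_profiles(field)
        assert binned.count[0, 0, 16] == 1
        assert binned.count.sum() == 1
        # oracle: floor(1.06 / (2.5/38)) == 16
        assert int(np.floor(1.06e-3 / (2.5e-3 / 38))) == 16

    def test_right_edge_inclusive(self):
        field = self.make_single_point_field(2.5e-3)
        binned = bin_profiles(field)
        assert binned.count[0, 0, 37] == 1

    def test_identical_rp_fills_bins_with_that_value(self):
        t = 30
        l = np.linspace(0, 2.4e-3, t)[:, None, None]
        r = np.full((t, 1, 1), 7.7e4)
        field = RpProfileField(times=np.arange(t, dtype=float), l_dr=l,
                               r_p=r, valid=np.ones((t, 1, 1), bool))
        binned = bin_profiles(field)
        filled = binned.valid[0, 0]
        assert np.allclose(binned.rp_median[0, 0, filled], 7.7e4)

    def test_empty_bins_flagged(self):
        field = self.make_single_point_field(1.06e-3)
        binned = bin_profiles(field)
        assert binned.valid.sum() == 1
        assert np.isnan(binned.rp_median[0, 0, 0])

    def test_bin_edges_exact(self):
        assert BIN_EDGES.size == 39
        assert BIN_EDGES[0] == 0.0
        assert BIN_EDGES[-1] == 2.5e-3
        assert np.allclose(np.diff(BIN_EDGES), 2.5e-3 / 38)


class TestPoolCoordinates:
    def test_pooled_points_conserved(self, forward_clean):
        field = forward_clean.field
        pooled = pool_coordinates(field, (2, 2))
        assert pooled.l_dr.shape == (field.l_dr.shape[0] * 4,
                                     field.l_dr.shape[1] // 2,
                                     field.l_dr.shape[2] // 2)
        assert pooled.valid.sum() == field.valid.sum()

    def test_non_divisible_rejected(self, forward_clean):
        with pytest.raises(ValueError, match="divide"):
            pool_coordinates(forward_clean.field, (3, 2))
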