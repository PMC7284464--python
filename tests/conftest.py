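"""Shared fixtures: small phantom geometries and forward-simulated runs.

All fixtures are generated programmatically; nothing is read from disk.
The heavy forward runs (render -> extract -> regress) are session-scoped
and shared between the unit suites and the acceptance suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from spindry.endpoint import EndpointMap, SimulationConfig, predict_endpoints
from spindry.phantom import (
    GroundTruth,
    PhantomSpec,
    graded_thickness,
    simulate_series,
    uniform_thickness,
)
from spindry.resistance import (
    BinnedRpField,
    ProcessTrace,
    RpProfileField,
    bin_profiles,
    resistance_profile,
)
from spindry.tomo import LayerSeries, ScanGeometry, extract_layer_series

R_VIAL = 10.9e-3
VOXEL = 1.0e-4


def make_geometry(
    n_azimuth: int = 16,
    n_height: int = 8,
    h_vial: float = 3.2e-3,
    voxel: float = VOXEL,
    r_vial: float = R_VIAL,
    margin: float = 2.0e-3,
    scan_interval: float = 90.0,
) -> ScanGeometry:
    n_xy = int(np.ceil(2.0 * (r_vial + margin) / voxel))
    return ScanGeometry(
        voxel_size=voxel,
        n_x=n_xy, n_y=n_xy, n_z=int(round(h_vial / voxel)),
        n_radial=int(np.ceil(r_vial / voxel)) + 2,
        n_azimuth=n_azimuth, n_height=n_height,
        r_vial=r_vial, h_vial=h_vial, scan_interval=scan_interval,
    )


@pytest.fixture(scope="session")
def small_geom() -> ScanGeometry:
    return make_geometry()


# ---------------------------------------------------------------------------
# true resistance shapes for the parameter-recovery runs
# ---------------------------------------------------------------------------

# Magnitudes are kept within ~30% of each other: the vial-level balance
# shares one P_i across coordinates via the *median* profile, so a wild
# R_p spread would make the per-coordinate energy split inconsistent
# with the supplied power (the shapes stay qualitatively distinct).

def rp_shape_constant(l_dr):
    return np.full_like(np.asarray(l_dr, dtype=float), 1.0e5)


def rp_shape_linear(l_dr):
    return 8.5e4 + 2.0e7 * np.asarray(l_dr, dtype=float)


def rp_shape_cracklike(l_dr):
    l = np.asarray(l_dr, dtype=float)
    return 1.25e5 * (0.82 + 0.18 * np.exp(-l / 5.0e-4))


RP_SHAPES = (rp_shape_constant, rp_shape_linear, rp_shape_cracklike)


def build_truth_profiles(geometry: ScanGeometry,
                         thickness: np.ndarray) -> GroundTruth:
    """Assign one of the three shapes to each azimuth (cyclically)."""
    n, m = geometry.n_azimuth, geometry.n_height
    knots = np.linspace(0.0, float(thickness.max()) * 1.3 + 1e-4, 12)
    values = np.empty((n, m, knots.size))
    for a in range(n):
        values[a] = RP_SHAPES[a % 3](knots)
    return GroundTruth(initial_thickness=thickness,
                       rp_knots=knots, rp_values=values)


def shape_for_azimuth(a: int):
    return RP_SHAPES[a % 3]


@dataclass
class ForwardRun:
    """One full phantom -> extraction -> regression round trip."""

    geometry: ScanGeometry
    spec: PhantomSpec
    truth: GroundTruth
    sim_config: SimulationConfig
    endpoint_truth: EndpointMap
    series: LayerSeries
    field: RpProfileField
    binned: BinnedRpField
    frames: list


def _run_forward(noise_sd: float, seed: int) -> ForwardRun:
    # scans cover only partial drying (t_end ~ 860-1030 s): regressing
    # through a coordinate's own endpoint corrupts the profile tail
    geometry = make_geometry(n_azimuth=16, n_height=10, h_vial=4.0e-3,
                             scan_interval=40.0)
    thickness = graded_thickness(geometry, 2.0e-3, axial_gradient=0.10,
                                 eccentricity=0.03)
    truth_in = build_truth_profiles(geometry, thickness)
    spec = PhantomSpec(seed=seed, initial_thickness=thickness,
                       noise_sd=noise_sd,
                       scan_interval=geometry.scan_interval)
    sim_config = SimulationConfig(p_chamber=10.0, p_total=1.2, dt=20.0,
                                  bin_phi=1, bin_h=1)
    frames, truth = simulate_series(spec, geometry, truth_in, sim_config,
                                    n_frames=20)
    series = extract_layer_series(frames, geometry)
    tt = truth.interface_temperature
    trace = ProcessTrace(
        times=np.concatenate([[0.0], tt[:, 0] + sim_config.dt]),
        t_interface=np.concatenate([[tt[0, 1]], tt[:, 1]]),
        p_chamber=sim_config.p_chamber)
    field = resistance_profile(series, trace, geometry)
    binned = bin_profiles(field)
    # rebuild the endpoint map for ledger checks
    endpoint_truth = predict_endpoints(
        truth.rp_knots, truth.rp_values, thickness, sim_config, geometry,
        record_trajectory=True)
    return ForwardRun(geometry=geometry, spec=spec, truth=truth,
                      sim_config=sim_config, endpoint_truth=endpoint_truth,
                      series=series, field=field, binned=binned,
                      frames=frames)


@pytest.fixture(scope="session")
def forward_clean() -> ForwardRun:
    """Noise-free forward run with the three resistance shapes."""
    return _run_forward(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def forward_noisy() -> ForwardRun:
    """Same run at 5% greyscale noise."""
    return _run_forward(noise_sd=0.05, seed=12)


@pytest.fixture(scope="session")
def static_phantom(small_geom):
    """A single noise-free rendered frame with a graded thickness field."""
    from spindry.phantom import make_annulus_frame

    thickness = graded_thickness(small_geom, 2.0e-3, axial_gradient=0.15,
                                 eccentricity=0.05)
    spec = PhantomSpec(seed=5, initial_thickness=thickness)
    frame = make_annulus_frame(spec, small_geom)
    return spec, small_geom, thickness, frame
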