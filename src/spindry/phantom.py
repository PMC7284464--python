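"""Synthetic 4D-CT phantom of a spin-frozen vial, with known ground truth.

Renders cartesian greyscale volumes containing a glass wall and an
annular frozen layer of prescribed per-(phi, h) thickness, with optional
cracks, internal cavities and gripper spots, partial-volume weighted
boundary voxels and seeded gaussian noise.  A forward drying simulation
(driven by the endpoint stepper) produces time series of shrinking
annuli together with the realised endpoints, and a thermal-camera model
renders rotation-synchronised surface-temperature movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .endpoint import EndpointMap, SimulationConfig, predict_endpoints
from .physics import DEFAULT_CONSTANTS, PhysicalConstants
from .tomo import ScanGeometry, VolumeFrame

__all__ = [
    "Defect",
    "PhantomSpec",
    "GroundTruth",
    "ThermalCameraSpec",
    "ThermalMovie",
    "uniform_thickness",
    "graded_thickness",
    "make_annulus_frame",
    "simulate_series",
    "make_thermal_movie",
]


@dataclass(frozen=True)
class Defect:
    """A localized departure from the ideal annulus.

    kind:
      * ``crack``        — radial planar gap fully penetrating the layer
                           over the (phi, h) range; ``radial_extent``
                           is ignored;
      * ``cavity``       — internal void of the given radial extent,
                           centred inside the local layer;
      * ``gripper_spot`` — local thickness reduction by ``radial_extent``.
    """

    kind: Literal["crack", "cavity", "gripper_spot"]
    phi_range: tuple[float, float]      # rad, [lo, hi) in [0, 2*pi)
    h_range: tuple[float, float]        # m
    radial_extent: float = 0.0          # m

    def __post_init__(self) -> None:
        if self.kind not in ("crack", "cavity", "gripper_spot"):
            raise ValueError(f"unknown defect kind {self.kind!r}")
        if self.kind != "crack" and self.radial_extent <= 0:
            raise ValueError(f"{self.kind} needs a positive radial_extent")


@dataclass
class PhantomSpec:
    """Everything needed to render one phantom deterministically."""

    seed: int
    initial_thickness: np.ndarray       # (n_azimuth, n_height), m
    defects: Sequence[Defect] = ()
    noise_sd: float = 0.0               # relative to the ice/air contrast
    attenuation: dict = field(
        default_factory=lambda: {"air": 0.0, "ice": 0.6, "glass": 1.0})
    glass_thickness: float = 1.0e-3     # m
    scan_interval: float = 176.11       # s

    def __post_init__(self) -> None:
        self.initial_thickness = np.asarray(self.initial_thickness,
                                            dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if np.any(self.initial_thickness < 0):
            raise ValueError("thickness must be non-negative")

    def validate_against(self, geometry: ScanGeometry) -> None:
        if self.initial_thickness.shape != (geometry.n_azimuth,
                                            geometry.n_height):
            raise ValueError(
                "thickness field shape "
                f"{self.initial_thickness.shape} does not match the "
                f"(n_azimuth, n_height) = "
                f"({geometry.n_azimuth}, {geometry.n_height}) grid"
            )
        if np.any(self.initial_thickness > geometry.r_vial):
            raise ValueError("thickness exceeds the inner vial radius")
        for d in self.defects:
            if d.kind == "cavity":
                sel = _defect_mask_thickness(d, self.initial_thickness,
                                             geometry)
                if np.any(d.radial_extent >= self.initial_thickness[sel]):
                    raise ValueError(
                        "cavity radial extent must be smaller than the "
                        "local layer thickness")


@dataclass
class GroundTruth:
    """What the phantom actually contains, for oracle checks downstream."""

    initial_thickness: np.ndarray           # (n, m) m
    rp_knots: np.ndarray                    # (K,) m, L_dr knots
    rp_values: np.ndarray                   # (n, m, K) m/s
    endpoints: np.ndarray | None = None     # (n, m) s, realised t_end
    interface_temperature: np.ndarray | None = None   # (steps, 2): t, T_i
    sublimed_volume_per_frame: np.ndarray | None = None   # (T,) m^3

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rp_values) <= 0):
            raise ValueError("ground-truth R_p values must be positive")
        if self.endpoints is not None:
            e = np.asarray(self.endpoints, dtype=float)
            bad = (np.asarray(self.initial_thickness) > 0) \
                & np.isfinite(e) & (e <= 0)
            if np.any(bad):
                raise ValueError("endpoints must be > 0 where ice exists")


# ---------------------------------------------------------------------------
# thickness-field constructors
# ---------------------------------------------------------------------------

def uniform_thickness(geometry: ScanGeometry, value: float) -> np.ndarray:
    """Constant initial thickness field."""
    return np.full((geometry.n_azimuth, geometry.n_height), float(value))


def graded_thickness(
    geometry: ScanGeometry,
    base: float,
    axial_gradient: float = 0.0,
    eccentricity: float = 0.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Thickness with a linear top-bottom gradient and azimuthal eccentricity.

    ``axial_gradient`` g makes the bottom thicker and the top thinner by
    +-g/2 of ``base`` (spin freezing leaves more product near the vial
    bottom); ``eccentricity`` adds ``base * e * cos(phi - phase)``,
    emulating a vial spun slightly off its true centre.
    """
    h_rel = (geometry.h_centers / geometry.h_vial)[None, :]   # 0 bottom
    phi = geometry.phi_centers[:, None]
    t = base * (1.0 + axial_gradient * (0.5 - h_rel)
                + eccentricity * np.cos(phi - phase))
    return np.broadcast_to(t, (geometry.n_azimuth, geometry.n_height)).copy()


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _defect_mask_thickness(defect: Defect, thickness: np.ndarray,
                           geometry: ScanGeometry) -> np.ndarray:
    """(n, m) boolean selector of the defect's (phi, h) footprint."""
    phi = geometry.phi_centers[:, None]
    h = geometry.h_centers[None, :]
    lo, hi = defect.phi_range
    if lo <= hi:
        in_phi = (phi >= lo) & (phi < hi)
    else:                                   # wraps through 0
        in_phi = (phi >= lo) | (phi < hi)
    in_h = (h >= defect.h_range[0]) & (h < defect.h_range[1])
    return np.broadcast_to(in_phi & in_h, thickness.shape)


def _band_coverage(r: np.ndarray, r_lo, r_hi, dv: float) -> np.ndarray:
    """Partial-volume coverage of radial band [r_lo, r_hi] at radii ``r``.

    Linear ramp over one voxel at each boundary; exact for straight
    interfaces, adequate for the gently curved annulus.
    """
    return (np.clip((r - r_lo) / dv + 0.5, 0.0, 1.0)
            * np.clip((r_hi - r) / dv + 0.5, 0.0, 1.0))


def make_annulus_frame(
    spec: PhantomSpec,
    geometry: ScanGeometry,
    thickness_field: np.ndarray | None = None,
    axis_center: tuple[float, float] | None = None,
    timestamp: float = 0.0,
    frame_index: int = 0,
) -> VolumeFrame:
    """Render one cartesian greyscale volume of the vial.

    Glass occupies [r_vial, r_vial + glass_thickness]; ice occupies
    [r_vial - thickness(phi, h), r_vial] minus carved defects.  Boundary
    voxels get area-weighted greyscale.  Noise is seeded from
    ``(spec.seed, frame_index)`` so series are deterministic frame by
    frame.
    """
    thickness = (spec.initial_thickness if thickness_field is None
                 else np.asarray(thickness_field, dtype=float))
    if thickness.shape != (geometry.n_azimuth, geometry.n_height):
        raise ValueError("thickness field shape does not match the "
                         "(n_azimuth, n_height) grid")
    if np.any(thickness > geometry.r_vial) or np.any(thickness < 0):
        raise ValueError("thickness must lie in [0, r_vial]")

    vs = geometry.voxel_size
    cx, cy = ((geometry.n_x / 2.0, geometry.n_y / 2.0)
              if axis_center is None else axis_center)

    x = (np.arange(geometry.n_x) + 0.5 - cx) * vs
    y = (np.arange(geometry.n_y) + 0.5 - cy) * vs
    xx, yy = np.meshgrid(x, y)              # (ny, nx)
    r = np.hypot(xx, yy)
    phi = np.mod(np.arctan2(yy, xx), 2.0 * np.pi)
    phi_bin = np.minimum((phi / (2.0 * np.pi) * geometry.n_azimuth)
                         .astype(int), geometry.n_azimuth - 1)

    # apply gripper spots as thickness reductions up front
    t_field = thickness.copy()
    for d in spec.defects:
        if d.kind == "gripper_spot":
            sel = _defect_mask_thickness(d, t_field, geometry)
            t_field[sel] = np.clip(t_field[sel] - d.radial_extent, 0.0, None)

    lvl = spec.attenuation
    r_vial = geometry.r_vial
    cov_glass = _band_coverage(r, r_vial, r_vial + spec.glass_thickness, vs)

    data = np.empty((geometry.n_z, geometry.n_y, geometry.n_x),
                    dtype=np.float32)
    h_edges = np.linspace(0.0, geometry.h_vial, geometry.n_height + 1)
    for iz in range(geometry.n_z):
        h = (iz + 0.5) * vs
        if h >= geometry.h_vial:
            data[iz] = lvl["glass"] * cov_glass
            continue
        h_bin = min(int(np.searchsorted(h_edges, h, side="right")) - 1,
                    geometry.n_height - 1)
        t_slice = t_field[phi_bin, h_bin]
        r_in = r_vial - t_slice
        cov_ice = _band_coverage(r, r_in, r_vial, vs)
        cov_ice[t_slice <= 0] = 0.0
        for d in spec.defects:
            if not (d.h_range[0] <= h < d.h_range[1]):
                continue
            lo, hi = d.phi_range
            in_phi = ((phi >= lo) & (phi < hi)) if lo <= hi else \
                     ((phi >= lo) | (phi < hi))
            if d.kind == "crack":
                cov_ice[in_phi] = 0.0
            elif d.kind == "cavity":
                rc = 0.5 * (r_in + r_vial)
                cav = _band_coverage(r, rc - d.radial_extent / 2.0,
                                     rc + d.radial_extent / 2.0, vs)
                cov_ice[in_phi] = np.clip(cov_ice - cav, 0.0, 1.0)[in_phi]
        data[iz] = lvl["ice"] * cov_ice + lvl["glass"] * cov_glass

    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, frame_index])
        contrast = lvl["ice"] - lvl["air"]
        data += rng.normal(0.0, spec.noise_sd * contrast,
                           size=data.shape).astype(np.float32)
    return VolumeFrame(timestamp=timestamp, data=data)


# ---------------------------------------------------------------------------
# forward drying series
# ---------------------------------------------------------------------------

def simulate_series(
    spec: PhantomSpec,
    geometry: ScanGeometry,
    ground_truth: GroundTruth,
    sim_config: SimulationConfig,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    n_frames: int | None = None,
    axis_center: tuple[float, float] | None = None,
) -> tuple[list[VolumeFrame], GroundTruth]:
    """Render a drying series driven by the endpoint stepper.

    The true per-coordinate resistance profiles in ``ground_truth`` feed
    :func:`spindry.endpoint.predict_endpoints`; the resulting per-step
    dried-thickness trajectories are sampled at every ``scan_interval``
    and rendered as volumes.  Returns the frames and a ground truth
    completed with realised endpoints, the interface-temperature trace
    and the per-frame sublimed-volume ledger.
    """
    spec.validate_against(geometry)
    l_ice0 = spec.initial_thickness
    result = predict_endpoints(
        ground_truth.rp_knots, ground_truth.rp_values, l_ice0,
        sim_config, geometry, constants, record_trajectory=True)
    traj = result.l_dr_trajectory
    if traj is None:
        raise RuntimeError("stepper returned no trajectory")
    step_times = np.asarray(result.history["t"]) + sim_config.dt

    t_total = float(np.nanmax(result.t_end)) if np.isfinite(
        result.t_end).any() else sim_config.max_time
    if n_frames is None:
        n_frames = int(np.floor(t_total / spec.scan_interval)) + 2

    frames: list[VolumeFrame] = []
    sublimed = np.empty(n_frames)
    nm = geometry.segment_count
    seg_area_factor = np.pi * geometry.h_vial / nm
    r_p0 = geometry.r_vial - l_ice0
    for k in range(n_frames):
        t_k = k * spec.scan_interval
        l_dr_k = _interp_trajectory(traj, step_times, t_k)
        l_dr_k = np.minimum(l_dr_k, l_ice0)
        thickness_k = l_ice0 - l_dr_k
        frames.append(make_annulus_frame(
            spec, geometry, thickness_field=thickness_k,
            axis_center=axis_center, timestamp=t_k, frame_index=k))
        r_p_k = r_p0 + l_dr_k
        sublimed[k] = float(np.sum(
            seg_area_factor * (r_p_k ** 2 - r_p0 ** 2)))

    truth = GroundTruth(
        initial_thickness=l_ice0.copy(),
        rp_knots=np.asarray(ground_truth.rp_knots, dtype=float),
        rp_values=np.asarray(ground_truth.rp_values, dtype=float),
        endpoints=result.t_end,
        interface_temperature=np.column_stack([
            np.asarray(result.history["t"]),
            np.asarray(result.history["t_interface"])]),
        sublimed_volume_per_frame=sublimed,
    )
    return frames, truth


def _interp_trajectory(traj: np.ndarray, step_times: np.ndarray,
                       t: float) -> np.ndarray:
    """Linear interpolation of the (steps, n, m) L_dr trajectory at time t."""
    if t <= 0:
        return np.zeros_like(traj[0])
    if t >= step_times[-1]:
        return traj[-1]
    i = int(np.searchsorted(step_times, t))
    t0 = step_times[i - 1] if i > 0 else 0.0
    prev = traj[i - 1] if i > 0 else np.zeros_like(traj[0])
    w = (t - t0) / (step_times[i] - t0)
    return prev * (1 - w) + traj[i] * w


# ---------------------------------------------------------------------------
# thermal-camera model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ThermalCameraSpec:
    """Geometry and sampling of the verification thermal camera."""

    d_w: float = 0.15               # m, camera-to-vial distance
    fov_angle: float = 45.1         # degrees
    frame_rate: float = 1.0         # Hz
    rpm: float = 5.0                # vial rotation rate
    noise_sd: float = 0.0           # degC

    def __post_init__(self) -> None:
        if self.d_w <= 0:
            raise ValueError("d_w must be > 0")
        if not 0 < self.fov_angle < 180:
            raise ValueError("fov_angle must be in (0, 180) degrees")
        k = self.frame_rate * 60.0 / self.rpm
        if abs(k - round(k)) > 1e-9 or round(k) < 1:
            raise ValueError(
                "frame rate must give an integer number of frames per "
                f"revolution; got {k}")

    @property
    def frames_per_revolution(self) -> int:
        return int(round(self.frame_rate * 60.0 / self.rpm))

    @classmethod
    def from_dict(cls, block: dict) -> "ThermalCameraSpec":
        return cls(**block)


@dataclass
class ThermalMovie:
    """Rotation-synchronised surface-temperature frames.

    ``frames`` is (n_frames, n_height, width); the center column of each
    frame images the azimuth facing the camera at that instant.
    """

    frames: np.ndarray
    times: np.ndarray               # (n_frames,) s
    camera: ThermalCameraSpec


def make_thermal_movie(
    endpoints: np.ndarray,
    camera: ThermalCameraSpec,
    duration: float | None = None,
    t_cold: float = -25.0,
    t_heater: float = 40.0,
    ramp_rate: float = 0.1,         # degC/s after the local endpoint
    width: int = 5,
    seed: int = 0,
) -> ThermalMovie:
    """Render a thermal movie from a per-(phi, h) endpoint map (seconds).

    Each pixel stays at ``t_cold`` until its endpoint, then ramps at
    ``ramp_rate`` toward ``t_heater``.  Frame j faces azimuth
    ``2*pi*(j mod k)/k`` for k frames per revolution; the endpoint map is
    sampled at the nearest azimuth bin.  Degenerate (all-NaN or flat)
    maps simply produce flat movies.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    n_phi, n_h = endpoints.shape
    k = camera.frames_per_revolution
    if duration is None:
        ref = np.nanmax(endpoints) if np.isfinite(endpoints).any() else 0.0
        duration = ref + 20.0 * 60.0 / camera.rpm
    n_frames = int(np.ceil(duration * camera.frame_rate))
    times = np.arange(n_frames) / camera.frame_rate

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n_h, width), dtype=np.float32)
    half = width // 2
    for j in range(n_frames):
        phi_center = 2.0 * np.pi * (j % k) / k
        for c in range(width):
            phi = phi_center + (c - half) * (2.0 * np.pi / k) / width
            pbin = int(np.round(phi / (2.0 * np.pi) * n_phi)) % n_phi
            te = endpoints[pbin]
            temp = np.where(
                np.isfinite(te) & (times[j] >= te),
                np.minimum(t_cold + ramp_rate * (times[j] - te), t_heater),
                t_cold)
            frames[j, :, c] = temp
    if camera.noise_sd > 0:
        frames += rng.normal(0.0, camera.noise_sd,
                             size=frames.shape).astype(np.float32)
    return ThermalMovie(frames=frames, times=times, camera=camera)
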