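"""Configuration, orchestration and provenance for the full chain:
phantom -> extract -> radiality -> rp -> simulate -> thermal -> compare.

Every stage reads from and writes to a run directory; a single JSON/YAML
config with per-stage blocks governs a run, and identical config + seed
reproduce identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import io as sio
from .endpoint import SimulationConfig, predict_endpoints, spatial_bin
from .phantom import (
    Defect,
    GroundTruth,
    PhantomSpec,
    ThermalCameraSpec,
    graded_thickness,
    make_thermal_movie,
    simulate_series,
)
from .physics import PhysicalConstants
from .resistance import (
    ProcessTrace,
    bin_profiles,
    pool_coordinates,
    resistance_profile,
)
from .thermal import compare_endpoint_maps, detect_endpoint_map, unwrap_movie
from .tomo import ScanGeometry, extract_layer_series, radiality_map

__all__ = ["RunConfig", "run", "STAGES", "demo_config"]

log = logging.getLogger("spindry")

STAGES = ("phantom", "extract", "radiality", "rp", "simulate",
          "thermal", "compare")


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    voxel_size: float
    n_x: int
    n_y: int
    n_z: int
    n_radial: int
    n_azimuth: int
    n_height: int
    r_vial: float
    h_vial: float
    scan_interval: float = 176.11

    def build(self) -> ScanGeometry:
        return ScanGeometry(**self.model_dump())


class DefectBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["crack", "cavity", "gripper_spot"]
    phi_range: tuple[float, float]
    h_range: tuple[float, float]
    radial_extent: float = 0.0

    def build(self) -> Defect:
        return Defect(**self.model_dump())


class RpProfileBlock(BaseModel):
    """True resistance profile of the phantom (ground truth)."""

    model_config = ConfigDict(extra="forbid")
    kind: Literal["constant", "linear"] = "constant"
    value: float = 1.0e5            # m/s, constant level / linear start
    end_value: float = 2.0e5        # m/s, linear profiles only
    l_dr_max: float = 2.5e-3        # m, knot range

    def build(self, n: int, m: int) -> tuple[np.ndarray, np.ndarray]:
        knots = np.linspace(0.0, self.l_dr_max, 12)
        if self.kind == "constant":
            prof = np.full_like(knots, self.value)
        else:
            prof = np.linspace(self.value, self.end_value, knots.size)
        return knots, np.broadcast_to(prof, (n, m, knots.size)).copy()


class PhantomBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    base_thickness: float = 2.0e-3
    axial_gradient: float = 0.0
    eccentricity: float = 0.0
    noise_sd: float = 0.0
    defects: list[DefectBlock] = Field(default_factory=list)
    rp_profile: RpProfileBlock = Field(default_factory=RpProfileBlock)
    n_frames: Optional[int] = None
    glass_thickness: float = 1.0e-3


class SimulateBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_chamber: float = 10.0
    p_total: float = 1.2
    dt: float = 60.0
    bin_phi: int = 10
    bin_h: int = 10
    max_time: float = 43200.0

    def build(self) -> SimulationConfig:
        return SimulationConfig(**self.model_dump())


class ThermalBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    d_w: float = 0.15
    fov_angle: float = 45.1
    frame_rate: float = 1.0
    rpm: float = 5.0
    noise_sd: float = 0.0
    ramp_rate: float = 0.1
    t_cold: float = -25.0
    t_heater: float = 40.0

    def camera(self) -> ThermalCameraSpec:
        return ThermalCameraSpec(
            d_w=self.d_w, fov_angle=self.fov_angle,
            frame_rate=self.frame_rate, rpm=self.rpm,
            noise_sd=self.noise_sd)


class RunConfig(BaseModel):
    """Schema-validated configuration of a full or partial run."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    geometry: GeometryBlock
    physics: dict = Field(default_factory=dict)
    phantom: PhantomBlock = Field(default_factory=PhantomBlock)
    simulate: SimulateBlock = Field(default_factory=SimulateBlock)
    thermal: ThermalBlock = Field(default_factory=ThermalBlock)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def demo_config(scale: float = 1.0, seed: int = 0) -> RunConfig:
    """A small end-to-end demo: 16 x 10 coordinates, ~20 scans.

    ``scale`` < 1 shrinks the cartesian resolution further for very fast
    smoke runs.
    """
    voxel = 1.0e-4 / scale
    r_vial = 10.9e-3
    h_vial = 6.4e-3
    extent = 2 * (r_vial + 2.0e-3)
    n_xy = int(np.ceil(extent / voxel))
    return RunConfig(
        seed=seed,
        geometry=GeometryBlock(
            voxel_size=voxel, n_x=n_xy, n_y=n_xy,
            n_z=int(np.ceil(h_vial / voxel)),
            n_radial=int(np.ceil(r_vial / voxel)) + 2,
            n_azimuth=16, n_height=10,
            r_vial=r_vial, h_vial=h_vial, scan_interval=90.0),
        phantom=PhantomBlock(base_thickness=2.0e-3, axial_gradient=0.15,
                             eccentricity=0.05, noise_sd=0.02),
        simulate=SimulateBlock(bin_phi=2, bin_h=2, dt=30.0),
        thermal=ThermalBlock(frame_rate=16 * 5.0 / 60.0, rpm=5.0,
                             noise_sd=0.2),
    )


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _stage_phantom(cfg: RunConfig, rundir: Path) -> None:
    geom = cfg.geometry.build()
    pb = cfg.phantom
    thickness = graded_thickness(
        geom, pb.base_thickness, pb.axial_gradient, pb.eccentricity)
    spec = PhantomSpec(
        seed=cfg.seed, initial_thickness=thickness,
        defects=[d.build() for d in pb.defects],
        noise_sd=pb.noise_sd, glass_thickness=pb.glass_thickness,
        scan_interval=geom.scan_interval)
    knots, values = pb.rp_profile.build(geom.n_azimuth, geom.n_height)
    truth_in = GroundTruth(initial_thickness=thickness,
                           rp_knots=knots, rp_values=values)
    constants = PhysicalConstants.from_dict(cfg.physics)
    frames, truth = simulate_series(
        spec, geom, truth_in, cfg.simulate.build(), constants,
        n_frames=pb.n_frames)
    outdir = rundir / "phantom"
    sio.write_volume_series(frames, geom, outdir, seed=cfg.seed,
                            extra_meta={"ground_truth": "ground_truth.h5"})
    sio.write_ground_truth(truth, outdir / "ground_truth.h5")
    log.info("phantom: %d frames rendered", len(frames))


def _stage_extract(cfg: RunConfig, rundir: Path) -> None:
    frames, geom, _ = sio.read_volume_series(rundir / "phantom")
    series = extract_layer_series(frames, geom)
    outdir = rundir / "extract"
    outdir.mkdir(exist_ok=True)
    sio.write_layer_series(series, outdir / "layer_series.h5")
    sio.write_surface_map_csv(
        {"L_ice": series.l_ice, "L_ice_prime": series.l_ice_prime,
         "r_p": series.r_p},
        series.times, outdir / "surface_maps.csv")
    log.info("extract: %d scans -> %s grid", series.n_times,
             series.grid_shape)


def _stage_radiality(cfg: RunConfig, rundir: Path) -> None:
    series = sio.read_layer_series(rundir / "extract" / "layer_series.h5")
    rows = []
    for i, t in enumerate(series.times):
        res = radiality_map(series.l_ice[i], series.l_ice_prime[i])
        rows.append({
            "t": t,
            "max_rel_diff": float(np.nanmax(res.rel_diff))
            if res.defined.any() else np.nan,
            "exceed_fraction": res.exceed_fraction,
            "non_radial": res.non_radial,
        })
    outdir = rundir / "radiality"
    outdir.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(outdir / "radiality.csv", index=False)


def _stage_rp(cfg: RunConfig, rundir: Path) -> None:
    geom = cfg.geometry.build()
    constants = PhysicalConstants.from_dict(cfg.physics)
    series = sio.read_layer_series(rundir / "extract" / "layer_series.h5")
    truth = sio.read_ground_truth(
        rundir / "phantom" / "ground_truth.h5")
    if truth.interface_temperature is None:
        raise ValueError("ground truth lacks an interface-temperature trace")
    tt = truth.interface_temperature
    trace = ProcessTrace(
        times=np.concatenate([[0.0], tt[:, 0] + cfg.simulate.dt]),
        t_interface=np.concatenate([[tt[0, 1]], tt[:, 1]]),
        p_chamber=cfg.simulate.p_chamber)
    field = resistance_profile(series, trace, geom, constants)
    binned = bin_profiles(field)
    outdir = rundir / "rp"
    outdir.mkdir(exist_ok=True)
    sio.write_binned_profiles(binned, outdir / "profiles.h5")
    sio.binned_profiles_to_csv(binned, outdir / "profiles.csv")
    # pooled version on the simulation grid
    factors = (cfg.simulate.bin_phi, cfg.simulate.bin_h)
    pooled = bin_profiles(pool_coordinates(field, factors))
    sio.write_binned_profiles(pooled, outdir / "profiles_binned.h5")


def _stage_simulate(cfg: RunConfig, rundir: Path) -> None:
    geom = cfg.geometry.build()
    constants = PhysicalConstants.from_dict(cfg.physics)
    sim = cfg.simulate.build()
    series = sio.read_layer_series(rundir / "extract" / "layer_series.h5")
    pooled = sio.read_binned_profiles(
        rundir / "rp" / "profiles_binned.h5")
    l_ice0 = spatial_bin(series.l_ice[0], (sim.bin_phi, sim.bin_h))
    result = predict_endpoints(
        pooled.bin_centers, pooled.rp_median, l_ice0, sim, geom, constants,
        rp_valid=pooled.valid)
    outdir = rundir / "simulate"
    outdir.mkdir(exist_ok=True)
    sio.write_endpoint_csv(result.t_end_hours, outdir / "endpoints.csv")
    result.history.to_csv(outdir / "history.csv", index=False)
    log.info("simulate: t_end %.2f-%.2f h",
             np.nanmin(result.t_end_hours), np.nanmax(result.t_end_hours))


def _stage_thermal(cfg: RunConfig, rundir: Path) -> None:
    truth = sio.read_ground_truth(rundir / "phantom" / "ground_truth.h5")
    if truth.endpoints is None:
        raise ValueError("ground truth lacks realised endpoints")
    camera = cfg.thermal.camera()
    movie = make_thermal_movie(
        truth.endpoints, camera, seed=cfg.seed,
        t_cold=cfg.thermal.t_cold, t_heater=cfg.thermal.t_heater,
        ramp_rate=cfg.thermal.ramp_rate)
    traces = unwrap_movie(movie)
    measured = detect_endpoint_map(traces)
    outdir = rundir / "thermal"
    outdir.mkdir(exist_ok=True)
    sio.write_endpoint_csv(measured / 3600.0,
                           outdir / "measured_endpoints.csv")


def _stage_compare(cfg: RunConfig, rundir: Path) -> None:
    predicted = sio.read_endpoint_csv(
        rundir / "simulate" / "endpoints.csv")
    measured = sio.read_endpoint_csv(
        rundir / "thermal" / "measured_endpoints.csv")
    cmp = compare_endpoint_maps(predicted, measured)
    outdir = rundir / "compare"
    outdir.mkdir(exist_ok=True)
    (outdir / "comparison.json").write_text(json.dumps({
        "quantiles_predicted": cmp.quantiles_predicted,
        "quantiles_measured": cmp.quantiles_measured,
        "pearson_r": cmp.pearson_r,
        "max_cdf_distance": cmp.max_cdf_distance,
        "n_compared": cmp.n_compared,
    }, indent=2))
    pd.DataFrame({
        "bin_left_h": cmp.bin_edges[:-1],
        "bin_right_h": cmp.bin_edges[1:],
        "f_predicted": cmp.hist_predicted,
        "f_measured": cmp.hist_measured,
    }).to_csv(outdir / "histograms.csv", index=False)


_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "extract": _stage_extract,
    "radiality": _stage_radiality,
    "rp": _stage_rp,
    "simulate": _stage_simulate,
    "thermal": _stage_thermal,
    "compare": _stage_compare,
}


def run(config: RunConfig, outdir: str | Path,
        stages: Sequence[str] | None = None) -> Path:
    """Execute the selected stages in dependency order.

    Writes a ``metadata.json`` with the config hash, seed and library
    versions; stages write into per-stage subdirectories of ``outdir``.
    """
    logging.basicConfig(level=config.log_level)
    rundir = Path(outdir)
    rundir.mkdir(parents=True, exist_ok=True)
    selected = list(stages) if stages is not None else config.stages
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    import scipy
    (rundir / "metadata.json").write_text(json.dumps({
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [s for s in STAGES if s in selected],
        "versions": {"numpy": np.__version__, "scipy": scipy.__version__},
        "config": config.model_dump(mode="json"),
    }, indent=2, sort_keys=True))

    for stage in STAGES:            # dependency order
        if stage in selected:
            log.info("running stage %s", stage)
            _STAGE_FUNCS[stage](config, rundir)
    return rundir
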