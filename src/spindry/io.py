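"""File formats: TIFF volume stacks with JSON sidecars, HDF5 series and
profile containers, CSV surface maps."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .phantom import GroundTruth
from .resistance import BinnedRpField
from .tomo import LayerSeries, ScanGeometry, VolumeFrame

__all__ = [
    "write_volume_series",
    "read_volume_series",
    "write_layer_series",
    "read_layer_series",
    "write_surface_map_csv",
    "write_binned_profiles",
    "read_binned_profiles",
    "binned_profiles_to_csv",
    "write_ground_truth",
    "read_ground_truth",
    "write_endpoint_csv",
    "read_endpoint_csv",
]

FRAME_PATTERN = "frame_{t:05d}.tif"


def write_volume_series(
    frames: list[VolumeFrame],
    geometry: ScanGeometry,
    outdir: str | Path,
    seed: int | None = None,
    extra_meta: dict | None = None,
) -> Path:
    """Write one multi-page TIFF per time point plus a JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, frame in enumerate(frames):
        name = FRAME_PATTERN.format(t=i)
        tifffile.imwrite(outdir / name, frame.data)
        names.append(name)
    sidecar = {
        "frames": names,
        "timestamps": [float(f.timestamp) for f in frames],
        "geometry": geometry.to_dict(),
        "seed": seed,
    }
    if extra_meta:
        sidecar.update(extra_meta)
    path = outdir / "series.json"
    path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_volume_series(
    path: str | Path,
) -> tuple[list[VolumeFrame], ScanGeometry, dict]:
    """Read a TIFF series from its sidecar (file or containing directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / "series.json"
    meta = json.loads(path.read_text())
    geometry = ScanGeometry.from_dict(meta["geometry"])
    frames = [
        VolumeFrame(timestamp=t, data=tifffile.imread(path.parent / name))
        for name, t in zip(meta["frames"], meta["timestamps"])
    ]
    return frames, geometry, meta


def write_layer_series(series: LayerSeries, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("t", data=series.times)
        f.create_dataset("L_ice", data=series.l_ice)
        f.create_dataset("L_ice_prime", data=series.l_ice_prime)
        f.create_dataset("r_p", data=series.r_p)
        f.create_dataset("r_vial", data=np.asarray(series.r_vial))


def read_layer_series(path: str | Path) -> LayerSeries:
    with h5py.File(path, "r") as f:
        rv = f["r_vial"][()]
        return LayerSeries(
            times=f["t"][()],
            l_ice=f["L_ice"][()],
            l_ice_prime=f["L_ice_prime"][()],
            r_p=f["r_p"][()],
            r_vial=float(rv) if np.ndim(rv) == 0 else rv,
        )


def write_surface_map_csv(
    fields: dict[str, np.ndarray],
    times: np.ndarray,
    path: str | Path,
) -> None:
    """Long-format CSV: t, phi_index, h_index, one column per field."""
    t_n, n, m = next(iter(fields.values())).shape
    tt, pp, hh = np.meshgrid(np.arange(t_n), np.arange(n), np.arange(m),
                             indexing="ij")
    df = pd.DataFrame({
        "t": np.asarray(times)[tt.ravel()],
        "phi_index": pp.ravel(),
        "h_index": hh.ravel(),
    })
    for name, arr in fields.items():
        df[name] = arr.ravel()
    df.to_csv(path, index=False)


def write_binned_profiles(field: BinnedRpField, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("L_dr_bins", data=field.bin_edges)
        f.create_dataset("R_p_median", data=field.rp_median)
        f.create_dataset("count", data=field.count)
        f.create_dataset("valid", data=field.valid)


def read_binned_profiles(path: str | Path) -> BinnedRpField:
    with h5py.File(path, "r") as f:
        return BinnedRpField(
            bin_edges=f["L_dr_bins"][()],
            rp_median=f["R_p_median"][()],
            count=f["count"][()],
        )


def binned_profiles_to_csv(field: BinnedRpField, path: str | Path) -> None:
    """Tidy CSV of non-empty bins: phi_index, h_index, bin_center_mm, Rp."""
    n, m, b = field.rp_median.shape
    pp, hh, bb = np.meshgrid(np.arange(n), np.arange(m), np.arange(b),
                             indexing="ij")
    keep = field.valid.ravel()
    pd.DataFrame({
        "phi_index": pp.ravel()[keep],
        "h_index": hh.ravel()[keep],
        "bin_center_mm": field.bin_centers[bb.ravel()[keep]] * 1e3,
        "Rp_m_per_s": field.rp_median.ravel()[keep],
    }).to_csv(path, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("initial_thickness", data=truth.initial_thickness)
        f.create_dataset("rp_knots", data=truth.rp_knots)
        f.create_dataset("rp_values", data=truth.rp_values)
        for name in ("endpoints", "interface_temperature",
                     "sublimed_volume_per_frame"):
            value = getattr(truth, name)
            if value is not None:
                f.create_dataset(name, data=value)


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        def opt(name):
            return f[name][()] if name in f else None
        return GroundTruth(
            initial_thickness=f["initial_thickness"][()],
            rp_knots=f["rp_knots"][()],
            rp_values=f["rp_values"][()],
            endpoints=opt("endpoints"),
            interface_temperature=opt("interface_temperature"),
            sublimed_volume_per_frame=opt("sublimed_volume_per_frame"),
        )


def write_endpoint_csv(t_end_hours: np.ndarray, path: str | Path) -> None:
    n, m = t_end_hours.shape
    pp, hh = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    pd.DataFrame({
        "phi_index": pp.ravel(),
        "h_index": hh.ravel(),
        "t_end_h": t_end_hours.ravel(),
    }).to_csv(path, index=False)


def read_endpoint_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    n = df["phi_index"].max() + 1
    m = df["h_index"].max() + 1
    out = np.full((n, m), np.nan)
    out[df["phi_index"], df["h_index"]] = df["t_end_h"]
    return out
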