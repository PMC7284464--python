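"""Cylindrical re-gridding and frozen-layer extraction.

Cartesian reconstructed volumes are resampled onto an (r, phi, h) grid,
the frozen annulus is segmented by greyscale thresholding, and per-
(phi, h) layer metrics are extracted:

* ``L_ice``  — frozen thickness, wall radius minus innermost ice radius;
* ``L_ice'`` — integrated radial ice length (cavities excluded);
* their relative difference, which diagnoses non-radial sublimation.

Conventions: indices are 0-based; phi in [0, 2*pi) with bin centers,
phi = 0 on the +x axis, counterclockwise viewed from the vial top;
h = 0 at the vial bottom; radial bins have width ``voxel_size``.
Volumes are arrays indexed (z, y, x), voxel centers at (i + 0.5)*voxel_size.
"""

from __future__ import annotations

import contextlib
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "ScanGeometry",
    "VolumeFrame",
    "CylindricalFrame",
    "LayerSeries",
    "RadialityResult",
    "to_cylindrical",
    "estimate_axis",
    "segment_ice",
    "extract_radii",
    "integrated_length",
    "radiality_map",
    "extract_layer_series",
    "cylindrical_volume",
]


@dataclass(frozen=True)
class ScanGeometry:
    """Voxel, grid and vial dimensions for one scan series.

    ``n_azimuth`` and ``n_height`` are the azimuthal/height segmentation
    counts of the cylindrical grid; ``n_radial`` radial bins of width
    ``voxel_size`` must cover the inner wall radius ``r_vial``.
    """

    voxel_size: float               # m
    n_x: int
    n_y: int
    n_z: int
    n_radial: int
    n_azimuth: int
    n_height: int
    r_vial: float                   # m, inner vial-wall radius
    h_vial: float                   # m, analysed vial height
    scan_interval: float = 176.11   # s

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if min(self.n_x, self.n_y, self.n_z) < 1:
            raise ValueError("cartesian dims must be >= 1")
        if min(self.n_radial, self.n_azimuth, self.n_height) < 1:
            raise ValueError("cylindrical dims must be >= 1")
        if self.r_vial > self.n_radial * self.voxel_size:
            raise ValueError(
                "radial grid does not cover r_vial: "
                f"{self.n_radial} bins x {self.voxel_size} m "
                f"< r_vial = {self.r_vial} m"
            )
        if self.h_vial > self.n_z * self.voxel_size + 1e-12:
            raise ValueError("h_vial exceeds the scanned z extent")

    # -- derived grid quantities ------------------------------------------
    @property
    def dr(self) -> float:
        return self.voxel_size

    @property
    def dphi(self) -> float:
        return 2.0 * np.pi / self.n_azimuth

    @property
    def dh(self) -> float:
        return self.h_vial / self.n_height

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_radial) + 0.5) * self.dr

    @property
    def phi_centers(self) -> np.ndarray:
        return (np.arange(self.n_azimuth) + 0.5) * self.dphi

    @property
    def h_centers(self) -> np.ndarray:
        return (np.arange(self.n_height) + 0.5) * self.dh

    @property
    def segment_count(self) -> int:
        """n * m, the number of (phi, h) surface segments."""
        return self.n_azimuth * self.n_height

    def to_dict(self) -> dict:
        return {
            "voxel_size": self.voxel_size,
            "n_x": self.n_x, "n_y": self.n_y, "n_z": self.n_z,
            "n_radial": self.n_radial, "n_azimuth": self.n_azimuth,
            "n_height": self.n_height,
            "r_vial": self.r_vial, "h_vial": self.h_vial,
            "scan_interval": self.scan_interval,
        }

    @classmethod
    def from_dict(cls, block: dict) -> "ScanGeometry":
        return cls(**block)


@dataclass
class VolumeFrame:
    """One reconstructed greyscale volume, indexed (z, y, x)."""

    timestamp: float                # s
    data: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D (z, y, x)")


@dataclass
class CylindricalFrame:
    """Greyscale resampled onto the (r, phi, h) grid.

    ``valid`` flags bins whose center fell inside the cartesian footprint.
    """

    timestamp: float
    values: np.ndarray              # (n_radial, n_azimuth, n_height)
    valid: np.ndarray               # bool, same shape

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("values/valid shape mismatch")


@dataclass
class RadialityResult:
    """Per-coordinate (L_ice - L_ice') / L_ice with a non-radiality verdict."""

    rel_diff: np.ndarray            # (n_azimuth, n_height); NaN where undefined
    defined: np.ndarray             # bool
    non_radial: bool
    exceed_fraction: float          # area fraction with rel_diff > threshold
    threshold: float


@dataclass
class LayerSeries:
    """Per-scan layer metrics over the (phi, h) grid.

    Arrays are indexed (time, phi, h).  ``r_vial`` may be a scalar or a
    per-(phi, h) field (tilted-vial override).
    """

    times: np.ndarray               # (T,) s, strictly increasing
    l_ice: np.ndarray               # (T, n, m) m
    l_ice_prime: np.ndarray         # (T, n, m) m
    r_p: np.ndarray                 # (T, n, m) m
    r_vial: np.ndarray | float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("l_ice", "l_ice_prime", "r_p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.l_ice.shape:
                raise ValueError("field shape mismatch in LayerSeries")
        if self.l_ice.shape[0] != self.times.size:
            raise ValueError("time axis mismatch")
        rv = np.asarray(self.r_vial, dtype=float)
        eps = 1e-12
        if np.any(self.l_ice_prime > self.l_ice + eps):
            raise ValueError("invariant violated: L_ice' > L_ice")
        if np.any(self.l_ice > rv + eps):
            raise ValueError("invariant violated: L_ice > r_vial")
        if np.any(self.l_ice_prime < -eps):
            raise ValueError("invariant violated: L_ice' < 0")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.l_ice.shape[1:]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

@contextlib.contextmanager
def warnings_ignored():
    """Silence all-NaN slice warnings from nanmedian on empty columns."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        yield

def to_cylindrical(
    frame: VolumeFrame,
    geometry: ScanGeometry,
    axis_center: tuple[float, float],
    order: int = 1,
) -> CylindricalFrame:
    """Resample a cartesian volume onto the cylindrical bin-center grid.

    Parameters
    ----------
    axis_center : (cx, cy)
        Vial axis position in voxel units on the (x, y) plane
        (physical position / voxel_size).
    order : int
        Interpolation order; 1 (linear) by default, 0 for binary inputs.

    Bins whose center lies outside the cartesian footprint are flagged
    invalid and hold NaN.
    """
    cx, cy = axis_center
    if not (0 <= cx <= geometry.n_x and 0 <= cy <= geometry.n_y):
        raise ValueError(f"axis center {axis_center} outside volume footprint")

    vs = geometry.voxel_size
    r = geometry.r_centers[:, None, None] / vs          # voxel units
    phi = geometry.phi_centers[None, :, None]
    h = geometry.h_centers[None, None, :] / vs

    # voxel center i sits at physical (i + 0.5) * voxel_size
    x_idx = cx + r * np.cos(phi) - 0.5
    y_idx = cy + r * np.sin(phi) - 0.5
    z_idx = h - 0.5

    shape = (geometry.n_radial, geometry.n_azimuth, geometry.n_height)
    coords = np.stack([
        np.broadcast_to(z_idx, shape).ravel(),
        np.broadcast_to(y_idx, shape).ravel(),
        np.broadcast_to(x_idx, shape).ravel(),
    ])
    values = ndimage.map_coordinates(
        frame.data.astype(np.float64), coords, order=order,
        mode="constant", cval=np.nan,
    ).reshape(shape)
    valid = np.isfinite(values)
    return CylindricalFrame(frame.timestamp, values, valid)


def estimate_axis(frame: VolumeFrame) -> tuple[float, float]:
    """Estimate the vial axis as the centroid of the glass-wall annulus.

    Two-stage Otsu: separate material from background, then glass (the
    brightest class) from ice.  Returns (cx, cy) in voxel units.
    """
    data = np.asarray(frame.data, dtype=float)
    finite = data[np.isfinite(data)]
    if finite.size == 0 or np.ptp(finite) == 0:
        raise ValueError("no annulus detected: volume has no contrast")
    thr_fg = threshold_otsu(finite)
    fg = finite[finite > thr_fg]
    if fg.size == 0 or np.ptp(fg) == 0:
        raise ValueError("no annulus detected: single foreground level")
    thr_glass = threshold_otsu(fg)
    mask = data > thr_glass
    if not mask.any():
        raise ValueError("no annulus detected above the glass threshold")
    _, yy, xx = np.nonzero(mask)
    # +0.5: voxel centers
    return (float(xx.mean()) + 0.5, float(yy.mean()) + 0.5)


def segment_ice(
    cyl: CylindricalFrame,
    geometry: ScanGeometry,
    threshold: float | str = "otsu",
    keep_largest: bool = True,
) -> np.ndarray:
    """Segment the frozen layer on the cylindrical grid.

    ``threshold`` is either a fixed greyscale value or ``"otsu"`` for an
    automatic bimodal split.  Bins at r >= r_vial (glass and beyond) and
    invalid bins are always excluded.  With ``keep_largest`` only the
    largest connected ice component survives, so an isolated noise speck
    near the axis cannot set the innermost radius.
    """
    inside = geometry.r_centers < geometry.r_vial
    candidate = cyl.valid & inside[:, None, None]

    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown threshold policy {threshold!r}")
        vals = cyl.values[candidate]
        if vals.size == 0 or np.ptp(vals) == 0:
            raise ValueError(
                "degenerate greyscale histogram: cannot auto-threshold"
            )
        thr = threshold_otsu(vals)
    else:
        thr = float(threshold)

    mask = candidate & (cyl.values > thr)
    if keep_largest and mask.any():
        labels = label(mask, connectivity=1)
        labels = _merge_azimuthal_seam(labels)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == counts.argmax()
    return mask


def _merge_azimuthal_seam(labels: np.ndarray) -> np.ndarray:
    """Union components touching across the phi = 0/2*pi seam.

    ``label`` does not know the azimuthal axis wraps; components adjacent
    through the seam are re-joined here with a small union-find.
    """
    a, b = labels[:, 0, :], labels[:, -1, :]
    touching = (a > 0) & (b > 0)
    if not touching.any():
        return labels
    parent = np.arange(labels.max() + 1)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in zip(a[touching].ravel(), b[touching].ravel()):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(parent.size)])
    return roots[labels]


def extract_radii(
    mask: np.ndarray,
    geometry: ScanGeometry,
    r_vial: np.ndarray | float | None = None,
    values: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Innermost ice radius r_p and frozen thickness L_ice per (phi, h).

    r_p is the inner edge of the innermost bin classified as ice (the ice
    closest to the vial center); L_ice = r_vial - r_p.  Columns without
    ice get r_p = r_vial and L_ice = 0.

    When the greyscale ``values`` of the cylindrical frame are supplied,
    the edge is refined to sub-voxel precision by integrating the
    partial-volume greyscale over a 5-bin window around the binary edge
    (attenuation integrated along r is proportional to ice length, so
    the integral locates the interface independent of interpolation
    smear).  The refinement is clipped to +-1 bin around the binary
    estimate.
    """
    if mask.shape != (geometry.n_radial, geometry.n_azimuth,
                      geometry.n_height):
        raise ValueError("mask dims do not match geometry")
    dr = geometry.dr
    rv = geometry.r_vial if r_vial is None else r_vial
    rv = np.broadcast_to(np.asarray(rv, dtype=float),
                         mask.shape[1:]).copy()
    has_ice = mask.any(axis=0)
    inner = mask.argmax(axis=0)     # first True along r
    r_p = np.where(has_ice, inner * dr, rv)

    if values is not None and has_ice.any():
        k = mask.shape[0]
        win = min(5, k)
        with warnings_ignored():
            ref = np.nanmedian(np.where(mask, values, np.nan), axis=0)
        lo = np.clip(inner - 2, 0, k - win)                 # (n, m)
        idx = lo[None, :, :] + np.arange(win)[:, None, None]
        cols = np.take_along_axis(np.nan_to_num(values), idx, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.clip(cols / ref[None, :, :], 0.0, 1.0).sum(axis=0)
        refined = (lo + win) * dr - s * dr
        ok = has_ice & np.isfinite(refined) & (ref > 0)
        refined = np.clip(refined, (inner - 1) * dr, (inner + 1) * dr)
        r_p = np.where(ok, refined, r_p)

    r_p = np.clip(r_p, 0.0, rv)
    l_ice = rv - r_p
    return r_p, l_ice


def integrated_length(mask: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Integrated radial ice length L_ice' per (phi, h).

    Sum of radial bin widths over bins classified as ice; internal
    cavities are not counted, so L_ice' <= L_ice.
    """
    return mask.sum(axis=0) * geometry.dr


def radiality_map(
    l_ice: np.ndarray,
    l_ice_prime: np.ndarray,
    threshold: float = 0.05,
    area_fraction: float = 0.05,
) -> RadialityResult:
    """Relative cavity fraction (L_ice - L_ice')/L_ice with a verdict.

    Coordinates with L_ice = 0 are undefined and excluded.  The frame is
    flagged non-radial when more than ``area_fraction`` of the defined
    area exceeds ``threshold``.
    """
    l_ice = np.asarray(l_ice, dtype=float)
    l_ice_prime = np.asarray(l_ice_prime, dtype=float)
    defined = l_ice > 0
    rel = np.full(l_ice.shape, np.nan)
    np.divide(l_ice - l_ice_prime, l_ice, out=rel, where=defined)
    if defined.any():
        exceed = float(np.mean(rel[defined] > threshold))
    else:
        exceed = 0.0
    return RadialityResult(
        rel_diff=rel,
        defined=defined,
        non_radial=exceed > area_fraction,
        exceed_fraction=exceed,
        threshold=threshold,
    )


def extract_layer_series(
    frames: Iterable[VolumeFrame],
    geometry: ScanGeometry,
    axis_center: tuple[float, float] | str = "auto",
    threshold: float | str = "otsu",
) -> LayerSeries:
    """Run conversion + segmentation + radii extraction over a scan series.

    ``axis_center="auto"`` estimates the axis once, from the first frame.
    """
    times, l_ice_all, l_prime_all, r_p_all = [], [], [], []
    center = axis_center
    for frame in frames:
        if isinstance(center, str):
            center = estimate_axis(frame)
        cyl = to_cylindrical(frame, geometry, center)
        mask = segment_ice(cyl, geometry, threshold=threshold)
        r_p, l_ice = extract_radii(mask, geometry, values=cyl.values)
        l_prime = integrated_length(mask, geometry)
        times.append(frame.timestamp)
        l_ice_all.append(l_ice)
        l_prime_all.append(np.minimum(l_prime, l_ice))
        r_p_all.append(r_p)
    if not times:
        raise ValueError("no frames supplied")
    return LayerSeries(
        times=np.asarray(times),
        l_ice=np.stack(l_ice_all),
        l_ice_prime=np.stack(l_prime_all),
        r_p=np.stack(r_p_all),
        r_vial=geometry.r_vial,
    )


def cylindrical_volume(values: np.ndarray, geometry: ScanGeometry) -> float:
    """Volume integral sum(v * r * dr * dphi * dh) over the cylindrical grid.

    NaNs count as zero, so invalid bins do not contribute.
    """
    v = np.nan_to_num(np.asarray(values, dtype=float))
    r = geometry.r_centers[:, None, None]
    return float(np.sum(v * r) * geometry.dr * geometry.dphi * geometry.dh)
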