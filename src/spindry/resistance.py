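"""Per-(phi, h) dried-product resistance regression from a layer series.

Pipeline: Savitzky-Golay smoothing of the frozen thickness over time,
per-segment annular volume, sublimation rate from the volume derivative,
projected sublimating area, and finally

    R_p = A_p * (P_i - P_c) / mdot_sub        [m/s]

paired with the dried thickness L_dr = L_ice,0 - L_ice and binned into
38 L_dr bins over [0, 2.5] mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .physics import DEFAULT_CONSTANTS, PhysicalConstants, vapor_pressure_ice
from .tomo import LayerSeries, ScanGeometry

__all__ = [
    "ProcessTrace",
    "RpProfileField",
    "BinnedRpField",
    "SG_WINDOW",
    "SG_ORDER",
    "BIN_EDGES",
    "smooth_thickness",
    "segment_volume",
    "sublimation_rate",
    "projected_area",
    "dried_thickness",
    "resistance_profile",
    "bin_profiles",
    "pool_coordinates",
]

SG_WINDOW = 15
SG_ORDER = 3

#: 38 dried-thickness bins over [0, 2.5] mm.
BIN_EDGES = np.linspace(0.0, 2.5e-3, 39)


@dataclass
class ProcessTrace:
    """Process conditions during the scan series.

    ``t_interface`` is the sublimation-front temperature (K) measured by
    a single thermocouple, assumed spatially uniform; ``p_chamber`` (Pa)
    may be a scalar or a same-length series.
    """

    times: np.ndarray
    t_interface: np.ndarray
    p_chamber: np.ndarray | float = 5.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.t_interface = np.asarray(self.t_interface, dtype=float)
        if self.times.shape != self.t_interface.shape:
            raise ValueError("times/t_interface length mismatch")

    def at(self, times: np.ndarray,
           clamp: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (T_i, P_c) to the given scan times.

        With ``clamp`` (default) times outside the trace hold the first/
        last recorded value; otherwise they are rejected.
        """
        t = np.asarray(times, dtype=float)
        if not clamp and (t.min() < self.times.min() - 1e-9
                          or t.max() > self.times.max() + 1e-9):
            raise ValueError("process trace does not cover the scan times")
        ti = np.interp(t, self.times, self.t_interface)
        pc = (np.interp(t, self.times, self.p_chamber)
              if np.ndim(self.p_chamber) else
              np.full_like(t, float(self.p_chamber)))
        return ti, pc


@dataclass
class RpProfileField:
    """Raw per-coordinate (L_dr, R_p, t) profiles on the (phi, h) grid.

    Arrays are (T, n, m); ``valid`` masks entries with positive
    sublimation rate and driving force.
    """

    times: np.ndarray
    l_dr: np.ndarray
    r_p: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.l_dr.shape == self.r_p.shape == self.valid.shape):
            raise ValueError("field shape mismatch")
        if np.any(self.r_p[self.valid] <= 0):
            raise ValueError("valid R_p entries must be positive")
        if not np.all(np.isfinite(self.r_p[self.valid])):
            raise ValueError("valid R_p entries must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.l_dr.shape[1:]


@dataclass
class BinnedRpField:
    """Per-coordinate per-bin median resistance.

    ``rp_median`` is (n, m, 38) with NaN in empty bins; ``count`` the
    number of pooled points per bin.
    """

    bin_edges: np.ndarray
    rp_median: np.ndarray
    count: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def valid(self) -> np.ndarray:
        return self.count > 0


def _require_window(n_times: int) -> None:
    if n_times < SG_WINDOW:
        raise ValueError(
            f"layer series has {n_times} time points; Savitzky-Golay "
            f"smoothing needs at least {SG_WINDOW}")


def _uniform_dt(times: np.ndarray) -> float:
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("scan times must be uniformly spaced")
    return float(dt[0])


def smooth_thickness(series: LayerSeries) -> LayerSeries:
    """Savitzky-Golay smoothing (order 3, window 15) of L_ice over time.

    Window ends are handled by polynomial fits on the truncated windows
    (``mode="interp"``).  The smoothed thickness is clipped to
    [0, r_vial] and r_p updated consistently; L_ice' is smoothed the
    same way and re-clipped below L_ice.
    """
    _require_window(series.n_times)
    rv = np.asarray(series.r_vial, dtype=float)
    l_smooth = savgol_filter(series.l_ice, SG_WINDOW, SG_ORDER,
                             axis=0, mode="interp")
    l_smooth = np.clip(l_smooth, 0.0, rv)
    lp_smooth = savgol_filter(series.l_ice_prime, SG_WINDOW, SG_ORDER,
                              axis=0, mode="interp")
    lp_smooth = np.clip(lp_smooth, 0.0, l_smooth)
    return LayerSeries(
        times=series.times.copy(),
        l_ice=l_smooth,
        l_ice_prime=lp_smooth,
        r_p=rv - l_smooth,
        r_vial=series.r_vial,
    )


def segment_volume(r_p, geometry: ScanGeometry):
    """Frozen volume per (phi, h) segment: pi*h/(n*m)*(r_vial^2 - r_p^2)."""
    r_p = np.asarray(r_p, dtype=float)
    if np.any(r_p > geometry.r_vial + 1e-15):
        raise ValueError("r_p exceeds r_vial")
    v = (np.pi * geometry.h_vial / geometry.segment_count
         * (geometry.r_vial ** 2 - r_p ** 2))
    return v if v.ndim else float(v)


def sublimation_rate(
    volumes: np.ndarray,
    times: np.ndarray,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    derivative: str = "savgol",
) -> tuple[np.ndarray, np.ndarray]:
    """Sublimation rate mdot = -dV/dt * rho_ice * theta_dried (kg/s).

    The volume derivative uses the Savitzky-Golay first derivative with
    the same (3, 15) window on a uniform time grid (``derivative=
    "central"`` switches to central differences).  Entries with
    non-positive rate (constant or noise-increasing volume) are masked
    invalid rather than reported negative.

    Returns ``(mdot, valid)``.
    """
    volumes = np.asarray(volumes, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = _uniform_dt(times)
    if derivative == "savgol":
        _require_window(times.size)
        dvdt = savgol_filter(volumes, SG_WINDOW, SG_ORDER, deriv=1,
                             delta=dt, axis=0, mode="interp")
    elif derivative == "central":
        dvdt = np.gradient(volumes, dt, axis=0)
    else:
        raise ValueError(f"unknown derivative estimator {derivative!r}")
    mdot = -dvdt * constants.rho_ice * constants.theta_dried
    # floor at SG round-off dust so a constant volume masks cleanly
    tol = (100 * np.finfo(float).eps * np.max(np.abs(volumes), initial=0.0)
           / dt * constants.rho_ice * constants.theta_dried)
    valid = mdot > tol
    return np.where(valid, mdot, np.nan), valid


def projected_area(r_p, geometry: ScanGeometry):
    """Center-facing projected area per segment: 2*pi*h/(n*m)*r_p."""
    r_p = np.asarray(r_p, dtype=float)
    a = 2.0 * np.pi * geometry.h_vial / geometry.segment_count * r_p
    return a if a.ndim else float(a)


def dried_thickness(l_ice0, l_ice_i):
    """Dried-layer thickness L_dr = L_ice,0 - L_ice,i, clamped at 0."""
    out = np.clip(np.asarray(l_ice0, dtype=float)
                  - np.asarray(l_ice_i, dtype=float), 0.0, None)
    return out if out.ndim else float(out)


def resistance_profile(
    series: LayerSeries,
    trace: ProcessTrace,
    geometry: ScanGeometry,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    derivative: str = "savgol",
    presmoothed: bool = False,
) -> RpProfileField:
    """Regress R_p(L_dr) for every (phi, h) coordinate of a layer series.

    Order of operations: smooth L_ice, compute per-segment volumes,
    differentiate to the sublimation rate, compute the projected area and
    the driving pressure from the front-temperature trace, then
    ``R_p = A_p * (P_i - P_c) / mdot``.  Coordinate-times with masked
    rate or with P_i <= P_c are invalid; an entirely invalid field is
    rejected.
    """
    smoothed = series if presmoothed else smooth_thickness(series)
    r_p = np.asarray(smoothed.r_vial, dtype=float) - smoothed.l_ice
    v = segment_volume(r_p, geometry)
    mdot, valid = sublimation_rate(v, smoothed.times, constants, derivative)
    a_p = projected_area(r_p, geometry)

    t_i, p_c = trace.at(smoothed.times)
    p_i = vapor_pressure_ice(t_i, constants)
    drive = (p_i - p_c)[:, None, None]
    valid = valid & (drive > 0) & (a_p > 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        rp = np.where(valid, a_p * drive / mdot, np.nan)
    if not valid.any():
        raise ValueError(
            "resistance regression produced no valid entries "
            "(no sublimation signal or zero driving force)")
    l_dr = dried_thickness(smoothed.l_ice[0], smoothed.l_ice)
    return RpProfileField(times=smoothed.times.copy(), l_dr=l_dr,
                          r_p=rp, valid=valid)


def bin_profiles(
    field: RpProfileField,
    bin_edges: np.ndarray = BIN_EDGES,
) -> BinnedRpField:
    """Per-coordinate per-bin median R_p over L_dr bins.

    Points exactly on the right edge of the last bin are assigned to it;
    empty bins carry NaN and count 0.
    """
    edges = np.asarray(bin_edges, dtype=float)
    n_bins = edges.size - 1
    idx = np.digitize(field.l_dr, edges) - 1
    on_last_edge = field.l_dr == edges[-1]
    idx[on_last_edge] = n_bins - 1
    in_range = (idx >= 0) & (idx < n_bins) & field.valid

    t, n, m = field.l_dr.shape
    rp_median = np.full((n, m, n_bins), np.nan)
    count = np.zeros((n, m, n_bins), dtype=int)
    for b in range(n_bins):
        sel = in_range & (idx == b)
        if not sel.any():
            continue
        vals = np.where(sel, field.r_p, np.nan)
        count[:, :, b] = sel.sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(vals, axis=0)
        rp_median[:, :, b] = med
    return BinnedRpField(bin_edges=edges, rp_median=rp_median, count=count)


def pool_coordinates(
    field: RpProfileField, factors: tuple[int, int]
) -> RpProfileField:
    """Spatially merge profiles by pooling raw points of each block.

    The (T, n, m) point clouds of an (f_phi x f_h) block are concatenated
    along the time axis, giving a (T*f_phi*f_h, n/f_phi, m/f_h) field
    ready for :func:`bin_profiles`.
    """
    f_phi, f_h = factors
    t, n, m = field.l_dr.shape
    if n % f_phi or m % f_h:
        raise ValueError(
            f"factors {factors} do not divide grid dims {(n, m)}")

    def pool(a):
        a = a.reshape(t, n // f_phi, f_phi, m // f_h, f_h)
        return a.transpose(0, 2, 4, 1, 3).reshape(
            t * f_phi * f_h, n // f_phi, m // f_h)

    return RpProfileField(
        times=np.repeat(field.times, f_phi * f_h),
        l_dr=pool(field.l_dr), r_p=pool(field.r_p), valid=pool(field.valid))
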