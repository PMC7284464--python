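"""Thermal-imaging verification of the endpoint distribution.

Field-of-view geometry, rotation-synchronised unwrapping of surface-
temperature movies into per-(phi, h) traces, per-pixel endpoint
detection from the sharp temperature rise, and comparison of predicted
vs measured endpoint maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np

from .phantom import ThermalCameraSpec, ThermalMovie

__all__ = [
    "TemperatureTraces",
    "EndpointComparison",
    "hfov",
    "unwrap_movie",
    "detect_endpoint",
    "detect_endpoint_map",
    "compare_endpoint_maps",
]


def hfov(d_w: float, fov_angle: float) -> float:
    """Horizontal field of view (m): 2 * d_w * tan(alpha/2).

    ``fov_angle`` (alpha) is in degrees.
    """
    if not 0 < fov_angle < 180:
        raise ValueError("fov_angle must be in (0, 180) degrees")
    if d_w <= 0:
        raise ValueError("d_w must be > 0")
    return 2.0 * d_w * np.tan(np.deg2rad(fov_angle) / 2.0)


@dataclass
class TemperatureTraces:
    """Per-(phi, h) surface-temperature traces, one sample per revolution.

    ``values`` is (n_azimuth, n_height, n_revolutions); the trace of
    azimuth index a is sampled at ``t = a/frame_rate + rev * period``
    with ``period = 60/rpm`` seconds.
    """

    values: np.ndarray
    period: float                   # s between samples of one pixel
    t0: np.ndarray                  # (n_azimuth,) first sample time per phi

    def times(self, phi_index: int) -> np.ndarray:
        return self.t0[phi_index] + np.arange(self.values.shape[2]) \
            * self.period


def unwrap_movie(movie: ThermalMovie,
                 camera: ThermalCameraSpec | None = None) -> TemperatureTraces:
    """Unwrap a rotation-synchronised movie into azimuthal traces.

    Frame j contributes its center vertical strip to azimuth
    ``2*pi*(j mod k)/k`` (k frames per revolution); every (phi, h) pixel
    thus gets exactly one sample per revolution and the k strips tile
    the full circle without overlap.
    """
    cam = camera or movie.camera
    k = cam.frames_per_revolution
    n_frames, n_h, width = movie.frames.shape
    n_rev = n_frames // k
    if n_rev < 1:
        raise ValueError("movie shorter than one revolution")
    center = movie.frames[: n_rev * k, :, width // 2]      # (frames, n_h)
    values = center.reshape(n_rev, k, n_h).transpose(1, 2, 0)
    return TemperatureTraces(
        values=np.ascontiguousarray(values, dtype=float),
        period=60.0 / cam.rpm,
        t0=np.arange(k) / cam.frame_rate,
    )


def detect_endpoint(
    values: np.ndarray,
    times: np.ndarray,
    k_sigma: float = 5.0,
    baseline_fraction: float = 0.25,
    smooth_window: int = 3,
) -> float:
    """Endpoint of one trace: first sharp rise above the baseline rate.

    The forward difference is smoothed with a centred moving average,
    the baseline rate statistics (median and a MAD-based robust sd) come
    from the first ``baseline_fraction`` of the record, and the endpoint
    is the first sample whose smoothed rate exceeds
    ``baseline + k_sigma * sd``.  Flat traces return NaN (undetected).
    Detection is invariant to adding a constant to the whole trace.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 samples to detect an endpoint")
    rate = np.diff(values)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        rate = np.convolve(rate, kernel, mode="same")
    n_base = max(4, int(np.floor(baseline_fraction * rate.size)))
    base = rate[:n_base]
    med = np.median(base)
    sd = 1.4826 * np.median(np.abs(base - med))
    threshold = med + k_sigma * sd + 1e-12
    above = np.flatnonzero(rate > threshold)
    if above.size == 0:
        return float("nan")
    return float(times[above[0] + 1])


def detect_endpoint_map(traces: TemperatureTraces, **kwargs) -> np.ndarray:
    """Apply :func:`detect_endpoint` to every (phi, h) pixel."""
    n_phi, n_h, _ = traces.values.shape
    out = np.empty((n_phi, n_h))
    for a in range(n_phi):
        t = traces.times(a)
        for j in range(n_h):
            out[a, j] = detect_endpoint(traces.values[a, j], t, **kwargs)
    return out


@dataclass
class EndpointComparison:
    """Summary statistics comparing two aligned endpoint maps (hours)."""

    quantiles_predicted: dict
    quantiles_measured: dict
    pearson_r: float
    max_cdf_distance: float
    bin_edges: np.ndarray
    hist_predicted: np.ndarray
    hist_measured: np.ndarray
    n_compared: int


def _align(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample the finer map to the coarser grid by block means."""
    if a.shape == b.shape:
        return a, b

    def coarsen(fine, coarse_shape):
        fy, fx = fine.shape
        cy, cx = coarse_shape
        if fy % cy or fx % cx:
            raise ValueError(
                f"cannot align maps of shapes {fine.shape} and "
                f"{coarse_shape}: no integer block factor")
        return np.nanmean(
            fine.reshape(cy, fy // cy, cx, fx // cx), axis=(1, 3))

    if a.size > b.size:
        return coarsen(a, b.shape), b
    return a, coarsen(b, a.shape)


def compare_endpoint_maps(
    predicted: np.ndarray,
    measured: np.ndarray,
    n_bins: int = 20,
) -> EndpointComparison:
    """Histogram/CDF comparison of predicted vs measured endpoint maps.

    Inputs are per-(phi, h) endpoint times in hours; NaNs (undetected or
    unconverged pixels) are dropped pairwise.  Reports 5/50/95% quantiles
    of each map, the Pearson correlation between aligned maps, shared-
    edge histograms and the maximum empirical-CDF distance.
    """
    p, q = _align(np.asarray(predicted, dtype=float),
                  np.asarray(measured, dtype=float))
    ok = np.isfinite(p) & np.isfinite(q)
    if not ok.any():
        raise ValueError("no overlapping finite endpoints to compare")
    pv, qv = p[ok], q[ok]

    lo = min(pv.min(), qv.min())
    hi = max(pv.max(), qv.max())
    if not (pv.max() >= qv.min() and qv.max() >= pv.min()):
        warn("endpoint maps have disjoint supports")
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    hist_p, _ = np.histogram(pv, bins=edges, density=True)
    hist_q, _ = np.histogram(qv, bins=edges, density=True)

    grid = np.sort(np.concatenate([pv, qv]))
    cdf_p = np.searchsorted(np.sort(pv), grid, side="right") / pv.size
    cdf_q = np.searchsorted(np.sort(qv), grid, side="right") / qv.size
    max_dist = float(np.max(np.abs(cdf_p - cdf_q)))

    if pv.size > 1 and np.std(pv) > 0 and np.std(qv) > 0:
        r = float(np.corrcoef(pv, qv)[0, 1])
    else:
        r = float("nan")

    def quants(x):
        q5, q50, q95 = np.percentile(x, [5, 50, 95])
        return {"q05": float(q5), "q50": float(q50), "q95": float(q95)}

    return EndpointComparison(
        quantiles_predicted=quants(pv),
        quantiles_measured=quants(qv),
        pearson_r=r,
        max_cdf_distance=max_dist,
        bin_edges=edges,
        hist_predicted=hist_p,
        hist_measured=hist_q,
        n_compared=int(ok.sum()),
    )
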