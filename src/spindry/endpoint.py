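"""Primary-drying endpoint prediction by coupled heat/mass-balance stepping.

At every time step one vial-level heat balance fixes the interface
temperature and vapour pressure shared by all (phi, h) coordinates; each
active coordinate then sublimes at its own rate set by its local
resistance profile, the front radius is advanced by inverting the
per-segment annular volume, and a coordinate converges when its dried
thickness reaches its initial frozen thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .physics import (
    DEFAULT_CONSTANTS,
    HeatBalanceState,
    PhysicalConstants,
    latent_heat,
    power_balance_residual,
    solve_interface_temperature,
    vapor_pressure_ice,
)

#: Bisection bracket for the interface temperature (K).
T_BRACKET = (180.0, 273.16)
from .tomo import ScanGeometry

__all__ = [
    "SimulationConfig",
    "EndpointMap",
    "spatial_bin",
    "rp_interpolator",
    "segment_volume_from_radius",
    "dried_thickness_from_volume",
    "predict_endpoints",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the endpoint simulation."""

    p_chamber: float = 10.0         # Pa
    p_total: float = 1.2            # W
    dt: float = 60.0                # s
    bin_phi: int = 10               # spatial binning factor, azimuth
    bin_h: int = 10                 # spatial binning factor, height
    max_time: float = 43200.0       # s
    rp_table_size: int = 512        # dense lookup resolution per profile
    #: "conserve": local A/R ratios set the split of the globally solved
    #: sublimation rate, so the step delivers exactly the balanced power;
    #: "local": per-coordinate rates taken literally from A*(P_i-P_c)/R_p,
    #: which lets profile heterogeneity create/destroy a few % of energy.
    energy_partition: str = "conserve"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")
        if self.bin_phi < 1 or self.bin_h < 1:
            raise ValueError("binning factors must be >= 1")
        if self.energy_partition not in ("conserve", "local"):
            raise ValueError(
                f"unknown energy_partition {self.energy_partition!r}")

    @classmethod
    def from_dict(cls, block: dict) -> "SimulationConfig":
        return cls(**block)


@dataclass
class EndpointMap:
    """Predicted (or measured) per-(phi, h) primary-drying endpoints.

    ``t_end`` is in seconds; ``t_end_hours`` converts for reporting.
    ``history`` carries the per-step vial-level trace.
    """

    t_end: np.ndarray                   # (n, m) s; NaN where unconverged
    converged: np.ndarray               # (n, m) bool
    history: pd.DataFrame | None = None
    l_dr_trajectory: np.ndarray | None = None   # (steps, n, m), optional

    @property
    def t_end_hours(self) -> np.ndarray:
        return self.t_end / 3600.0


def spatial_bin(field: np.ndarray, factors: tuple[int, int]) -> np.ndarray:
    """Block-mean a (phi, h) field by integer factors.

    A (1600, 1000) grid binned by (10, 10) becomes (160, 100).
    """
    f_phi, f_h = factors
    n, m = field.shape
    if n % f_phi or m % f_h:
        raise ValueError(
            f"binning factors {factors} do not divide grid dims {(n, m)}"
        )
    return field.reshape(n // f_phi, f_phi, m // f_h, f_h).mean(axis=(1, 3))


def rp_interpolator(
    l_dr: np.ndarray,
    r_p: np.ndarray,
    valid: np.ndarray | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Cubic-spline lookup R_p(L_dr) with clamped extrapolation.

    Outside the knot range the nearest endpoint value is returned.  With a
    single valid point the profile is constant; with none it is rejected.
    """
    l_dr = np.asarray(l_dr, dtype=float)
    r_p = np.asarray(r_p, dtype=float)
    if valid is None:
        valid = np.isfinite(l_dr) & np.isfinite(r_p)
    x, y = l_dr[valid], r_p[valid]
    if x.size == 0:
        raise ValueError("no valid (L_dr, R_p) points for this coordinate")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if x.size == 1:
        c = float(y[0])
        return lambda q: np.full_like(np.asarray(q, dtype=float), c)
    if x.size < 4:
        # not enough knots for a cubic; fall back to linear
        return lambda q: np.interp(np.asarray(q, dtype=float), x, y)
    spline = CubicSpline(x, y)
    lo, hi = x[0], x[-1]

    def f(q):
        q = np.clip(np.asarray(q, dtype=float), lo, hi)
        out = spline(q)
        return out if out.ndim else float(out)

    return f


def segment_volume_from_radius(
    r_p, geometry: ScanGeometry, n_segments: int | None = None
):
    """Frozen volume of one (phi, h) segment from its front radius.

    V = pi * h_vial / (n*m) * (r_vial**2 - r_p**2)
    """
    r_p = np.asarray(r_p, dtype=float)
    if np.any(r_p > geometry.r_vial + 1e-15):
        raise ValueError("r_p exceeds r_vial")
    nm = geometry.segment_count if n_segments is None else n_segments
    v = np.pi * geometry.h_vial / nm * (geometry.r_vial ** 2 - r_p ** 2)
    return v if v.ndim else float(v)


def dried_thickness_from_volume(
    v_sub, r_p0, geometry: ScanGeometry, n_segments: int | None = None
):
    """Dried thickness from cumulative sublimed volume of one segment.

    Exact inverse of the per-segment annular volume: the front moves
    outward, so

        r_p = sqrt(r_p0**2 + V * n*m / (pi * h_vial)),  L_dr = r_p - r_p0.
    """
    nm = geometry.segment_count if n_segments is None else n_segments
    r_p = np.sqrt(np.asarray(r_p0, dtype=float) ** 2
                  + np.asarray(v_sub, dtype=float) * nm
                  / (np.pi * geometry.h_vial))
    out = r_p - r_p0
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# dense per-coordinate R_p lookup
# ---------------------------------------------------------------------------

def _build_rp_table(
    knots: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray | None,
    l_dr_max: float,
    table_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Tabulate per-coordinate spline profiles on a shared dense grid.

    ``values`` is (n, m, K) over shared knots (K,).  Returns the grid
    (G,) and a (n*m, G) table.  Spline evaluation per coordinate happens
    once, here; the stepper then interpolates linearly in the table.
    """
    n, m, k = values.shape
    grid = np.linspace(0.0, max(l_dr_max, knots[np.isfinite(knots)].max()),
                       table_size)
    table = np.empty((n * m, table_size))
    flat = values.reshape(n * m, k)
    vflat = (np.isfinite(flat) if valid is None
             else valid.reshape(n * m, k) & np.isfinite(flat))
    for i in range(n * m):
        if not vflat[i].any():
            raise ValueError(
                f"coordinate {i} has no valid resistance points")
        pts = flat[i][vflat[i]]
        if np.any(pts <= 0):
            raise ValueError("R_p profiles must be positive everywhere")
        f = rp_interpolator(knots, flat[i], vflat[i])
        # cubic overshoot on noisy profiles can dip negative; floor at
        # half the smallest observed value of this coordinate
        table[i] = np.maximum(f(grid), 0.5 * pts.min())
    return grid, table


def _lookup(table: np.ndarray, grid: np.ndarray,
            q: np.ndarray) -> np.ndarray:
    """Vectorised linear interpolation of every row of ``table`` at q[i]."""
    dg = grid[1] - grid[0]
    pos = np.clip(q / dg, 0.0, len(grid) - 1.000001)
    i0 = pos.astype(int)
    w = pos - i0
    rows = np.arange(len(q))
    return table[rows, i0] * (1 - w) + table[rows, i0 + 1] * w


def predict_endpoints(
    rp_knots: np.ndarray,
    rp_values: np.ndarray,
    l_ice0: np.ndarray,
    config: SimulationConfig,
    geometry: ScanGeometry,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    rp_valid: np.ndarray | None = None,
    record_trajectory: bool = False,
) -> EndpointMap:
    """Time-step the coupled heat/mass balance to per-coordinate endpoints.

    Parameters
    ----------
    rp_knots, rp_values : arrays
        Shared L_dr knots (K,) and per-coordinate resistance values
        (n, m, K) in m/s; each coordinate profile is spline-interpolated
        with clamped extrapolation.
    l_ice0 : (n, m) array
        Initial frozen thickness (m) per coordinate, on the *simulation*
        grid (apply :func:`spatial_bin` beforehand if needed).
    record_trajectory : bool
        Store the per-step L_dr field (used by the phantom forward model).

    Notes
    -----
    Per step: (1) the vial-level balance is solved with the total active
    area and the median profile evaluated at the mean active dried
    thickness; (2) each active coordinate sublimes at
    ``mdot = A_p * (P_i - P_c) / R_p``; (3) the accumulated volume is
    converted back to dried thickness; (4) a coordinate converges when
    its sublimed volume reaches its initial segment volume, with the
    crossing time interpolated inside the step.
    """
    l_ice0 = np.asarray(l_ice0, dtype=float)
    n, m = l_ice0.shape
    if rp_values.shape[:2] != (n, m):
        raise ValueError("rp_values grid does not match l_ice0")
    nm = n * m

    grid, table = _build_rp_table(
        np.asarray(rp_knots, dtype=float), np.asarray(rp_values, dtype=float),
        rp_valid, float(l_ice0.max()) * 1.05 + 1e-9, config.rp_table_size)
    # vial-level profile: per-knot median over coordinates
    vial_profile = np.nanmedian(table, axis=0)

    r_vial = geometry.r_vial
    l0 = l_ice0.ravel()
    r_p0 = r_vial - l0
    if np.any(r_p0 < 0):
        raise ValueError("initial thickness exceeds r_vial")
    v0 = np.pi * geometry.h_vial / nm * (r_vial ** 2 - r_p0 ** 2)

    if config.p_total == 0:
        # degenerate case: no power, no sublimation, nothing converges
        zero = np.zeros((n, m))
        return EndpointMap(
            t_end=np.full((n, m), np.nan),
            converged=l_ice0 <= 0,
            history=pd.DataFrame([{
                "t": 0.0, "t_interface": np.nan, "p_interface": np.nan,
                "dh_sub": np.nan, "area_vial": 0.0, "rp_vial": np.nan,
                "l_dr_vial": 0.0, "energy_rate": 0.0, "mass_rate": 0.0,
                "residual": 0.0,
                "n_active": int((l_ice0 > 0).sum()),
            }]),
            l_dr_trajectory=(zero[None] if record_trajectory else None),
        )
    if config.p_total < 0:
        raise ValueError("p_total must be >= 0")

    active = l0 > 0
    v_sub = np.zeros(nm)
    l_dr = np.zeros(nm)
    t_end = np.full(nm, np.nan)
    t = 0.0
    dt = config.dt
    dg = grid[1] - grid[0]

    hist_rows = []
    traj = [] if record_trajectory else None

    while active.any() and t < config.max_time:
        r_p = r_p0 + l_dr
        area = 2.0 * np.pi * geometry.h_vial / nm * r_p
        area_act = area[active]
        a_vial = float(area_act.sum())
        l_dr_vial = float(l_dr[active].mean())
        rp_vial = float(np.interp(l_dr_vial, grid, vial_profile))

        try:
            state = solve_interface_temperature(
                config.p_total, a_vial, rp_vial, config.p_chamber, constants)
        except ValueError as exc:
            # Late in drying the active area shrinks until the supplied
            # power cannot be rejected below the triple point.  Clamp the
            # interface at the bracket top: sublimation proceeds at its
            # ceiling rate and the excess power is treated as lost.
            resid_hi = power_balance_residual(
                T_BRACKET[1], config.p_total, a_vial, rp_vial,
                config.p_chamber, constants)
            if resid_hi < 0:
                t_hi = T_BRACKET[1]
                state = HeatBalanceState(
                    t_interface=t_hi,
                    p_interface=vapor_pressure_ice(t_hi, constants),
                    dh_sub=latent_heat(t_hi, constants),
                    area_vial=a_vial, rp_vial=rp_vial,
                    residual=resid_hi)
            else:
                raise RuntimeError(
                    f"heat balance failed at t = {t:.0f} s "
                    f"(A = {a_vial:.3e} m^2, R_p = {rp_vial:.3e} m/s): "
                    f"{exc}"
                ) from exc

        rp_i = _lookup(table[active], grid, l_dr[active])
        mdot = area_act * (state.p_interface - config.p_chamber) / rp_i
        if config.energy_partition == "conserve":
            # the balanced total rate is re-partitioned by the local
            # A/R weights so no energy is created by profile spread
            total = (state.area_vial
                     * (state.p_interface - config.p_chamber)
                     / state.rp_vial)
            mdot *= total / mdot.sum()
        dv = mdot * dt / (constants.theta_dried * constants.rho_ice)

        v_prev = v_sub[active]
        v_new = v_prev + dv
        banked = np.minimum(v_new, v0[active]) - v_prev
        # crossing inside this step: interpolate the endpoint time
        crossed = v_new >= v0[active]
        if crossed.any():
            frac = (v0[active] - v_prev) / dv
            idx = np.flatnonzero(active)[crossed]
            t_end[idx] = t + frac[crossed] * dt
        v_sub[active] = np.minimum(v_new, v0[active])
        l_dr = dried_thickness_from_volume(v_sub, r_p0, geometry, nm)
        # guard against fp round-off at full drying
        l_dr = np.minimum(l_dr, l0)

        energy_rate = float(
            (mdot * state.dh_sub / constants.molar_mass_water).sum())
        mass_rate = float(banked.sum()
                          * constants.theta_dried * constants.rho_ice / dt)
        hist_rows.append({
            "t": t, "t_interface": state.t_interface,
            "p_interface": state.p_interface, "dh_sub": state.dh_sub,
            "area_vial": a_vial, "rp_vial": rp_vial,
            "l_dr_vial": l_dr_vial, "energy_rate": energy_rate,
            "mass_rate": mass_rate, "residual": state.residual,
            "n_active": int(active.sum()),
        })
        if traj is not None:
            traj.append(l_dr.reshape(n, m).copy())

        active = active & ~np.isfinite(t_end)
        t += dt

    converged = np.isfinite(t_end) | (l0 <= 0)
    return EndpointMap(
        t_end=t_end.reshape(n, m),
        converged=converged.reshape(n, m),
        history=pd.DataFrame(hist_rows),
        l_dr_trajectory=np.stack(traj) if traj else None,
    )
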