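"""Empirical material physics for ice sublimation.

Vapour pressure of ice and latent heat of sublimation are evaluated from
empirical temperature correlations; the vial-level power balance

    P_tot = A_p,vial * (P_i - P_c) / R_p,vial * dH_sub / M

is solved for the sublimation-interface temperature by bracketed bisection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "PhysicalConstants",
    "HeatBalanceState",
    "DEFAULT_CONSTANTS",
    "vapor_pressure_ice",
    "latent_heat",
    "solve_interface_temperature",
]

#: Valid range of the empirical correlations (K); evaluation outside warns.
T_VALID_MIN = 150.0
T_VALID_MAX = 273.16


@dataclass(frozen=True)
class PhysicalConstants:
    """Empirical coefficients and material constants.

    Vapour-pressure coefficients (``alpha_pi`` .. ``delta_pi``) parameterise

        P_i = exp(alpha_pi - beta_pi/T + gamma_pi*ln(T) - delta_pi*T)   [Pa]

    with ``beta_pi`` in K and ``delta_pi`` in 1/K.  Latent-heat coefficients
    (``alpha_h`` .. ``eps_h``) parameterise

        dH_sub = alpha_h + beta_h*T - gamma_h*T**2
                 + delta_h*exp(-(T/eps_h)**2)                        [J/mol]
    """

    alpha_pi: float = 9.550426
    beta_pi: float = 5723.2658          # K
    gamma_pi: float = 3.53068
    delta_pi: float = 0.00728332        # 1/K
    alpha_h: float = 4.68e4             # J/mol
    beta_h: float = 35.9                # J/(mol K)
    gamma_h: float = 0.0741             # J/(mol K^2)
    delta_h: float = 542.0              # J/mol
    eps_h: float = 124.0                # K
    rho_ice: float = 918.0              # kg/m^3
    theta_dried: float = 0.97           # dried-layer porosity (-)
    molar_mass_water: float = 18.01528e-3   # kg/mol

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"constant {f.name!r} must be positive")

    @classmethod
    def from_dict(cls, block: dict) -> "PhysicalConstants":
        """Build constants from a JSON/YAML ``physics`` config block.

        Unknown keys are rejected; missing keys keep their defaults.
        """
        known = {f.name for f in fields(cls)}
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown physics constants: {sorted(unknown)}")
        return cls(**block)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_overrides(self, **kwargs) -> "PhysicalConstants":
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class HeatBalanceState:
    """Converged vial-level heat/mass balance at one instant."""

    t_interface: float          # K
    p_interface: float          # Pa, vapour pressure at the front
    dh_sub: float               # J/mol
    area_vial: float            # m^2, total sublimating area
    rp_vial: float              # m/s, vial-level resistance
    l_dr_vial: float = float("nan")   # m, mean dried thickness of active coords
    residual: float = float("nan")    # W, power-balance residual at solution


def _check_temperature(t_i, name: str = "t_i") -> np.ndarray:
    t = np.asarray(t_i, dtype=float)
    if np.any(t <= 0):
        raise ValueError(f"{name} must be positive (K); got minimum {t.min()}")
    if np.any((t < T_VALID_MIN) | (t > T_VALID_MAX)):
        warnings.warn(
            f"{name} outside correlation range "
            f"[{T_VALID_MIN}, {T_VALID_MAX}] K",
            stacklevel=3,
        )
    return t


def vapor_pressure_ice(t_i, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Saturation vapour pressure of ice (Pa) at temperature ``t_i`` (K).

    Clausius–Clapeyron-type empirical correlation; reproduces the
    triple-point pressure 611.657 Pa at 273.16 K to better than 0.5%.
    Accepts scalars or arrays.
    """
    t = _check_temperature(t_i)
    c = constants
    p = np.exp(c.alpha_pi - c.beta_pi / t + c.gamma_pi * np.log(t)
               - c.delta_pi * t)
    return p if p.ndim else float(p)


def latent_heat(t_i, constants: PhysicalConstants = DEFAULT_CONSTANTS):
    """Molar latent heat of ice sublimation (J/mol) at ``t_i`` (K)."""
    t = _check_temperature(t_i)
    c = constants
    dh = (c.alpha_h + c.beta_h * t - c.gamma_h * t ** 2
          + c.delta_h * np.exp(-((t / c.eps_h) ** 2)))
    return dh if dh.ndim else float(dh)


def power_balance_residual(
    t_i: float,
    p_total: float,
    area_vial: float,
    rp_vial: float,
    p_chamber: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Signed residual (W) of the vial power balance at temperature ``t_i``.

    Positive when the interface at ``t_i`` would reject more latent-heat
    power than ``p_total`` supplies.  Strictly increasing in ``t_i``.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_i = vapor_pressure_ice(t_i, constants)
        dh = latent_heat(t_i, constants)
    mdot = area_vial * (p_i - p_chamber) / rp_vial
    return mdot * dh / constants.molar_mass_water - p_total


def solve_interface_temperature(
    p_total: float,
    area_vial: float,
    rp_vial: float,
    p_chamber: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    bracket: tuple[float, float] = (180.0, 273.16),
    tol: float = 1e-9,
    max_iter: int = 200,
) -> HeatBalanceState:
    """Solve the vial heat balance for the interface temperature.

    Parameters
    ----------
    p_total : float
        Power delivered to the vial (W), > 0.
    area_vial : float
        Total sublimating area (m^2), > 0.
    rp_vial : float
        Vial-level dried-product resistance (m/s), > 0.
    p_chamber : float
        Chamber pressure (Pa).
    bracket : tuple
        Temperature bracket (K) for bisection.
    tol : float
        Absolute power-residual tolerance (W).

    Returns
    -------
    HeatBalanceState
        With ``residual`` guaranteed ``<= tol`` in magnitude.

    Raises
    ------
    ValueError
        On non-positive inputs or when the residual does not change sign
        over the bracket (the requested power is unreachable there).
    """
    if p_total <= 0:
        raise ValueError("p_total must be > 0")
    if area_vial <= 0:
        raise ValueError("area_vial must be > 0")
    if rp_vial <= 0:
        raise ValueError("rp_vial must be > 0")

    def f(t: float) -> float:
        return power_balance_residual(
            t, p_total, area_vial, rp_vial, p_chamber, constants)

    lo, hi = bracket
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0 or f_hi < 0:
        raise ValueError(
            "heat balance has no root in bracket "
            f"[{lo}, {hi}] K: residual({lo})={f_lo:.3e} W, "
            f"residual({hi})={f_hi:.3e} W; p_total={p_total} W is "
            "unreachable with the given area/resistance/pressure"
        )

    mid = 0.5 * (lo + hi)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = f(mid)
        if abs(f_mid) <= tol:
            break
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    else:
        f_mid = f(mid)
        if abs(f_mid) > tol:
            raise RuntimeError(
                f"bisection did not reach tolerance {tol} W "
                f"(residual {f_mid:.3e} W after {max_iter} iterations)"
            )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return HeatBalanceState(
            t_interface=mid,
            p_interface=vapor_pressure_ice(mid, constants),
            dh_sub=latent_heat(mid, constants),
            area_vial=area_vial,
            rp_vial=rp_vial,
            residual=f_mid,
        )
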