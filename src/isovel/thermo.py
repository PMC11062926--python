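"""Moist adiabatic lapse rate (MALRT) from first principles.

The lapse rate along a mountain slope is shallower in moist air than in dry
air because condensing water vapour releases latent heat as a parcel rises.
The moist adiabatic rate is

    Gamma_w = g * (1 + H_v * gamma / (R_sd * T))
                / (C_pd + H_v**2 * gamma * epsilon / (R_sd * T**2))

in K/m, where ``gamma = epsilon * e / (p - e)`` is the mixing ratio of water
vapour mass to dry-air mass, ``e`` the water vapour pressure and ``p`` the
air pressure.  In the dry limit (e = 0) this reduces to g / C_pd, about
9.76 °C/km (9.8 to one decimal).  All public functions accept scalars or
NumPy arrays and return °C per km for lapse rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DecadalClimatology, Grid2D

__all__ = [
    "ThermoConstants",
    "MoistAirState",
    "DEFAULT_CONSTANTS",
    "barometric_pressure",
    "mixing_ratio",
    "malrt",
    "saturation_vapour_pressure",
    "malrt_grid",
]


@dataclass(frozen=True)
class ThermoConstants:
    """Physical constants of the moist adiabatic lapse-rate equation.

    Attributes
    ----------
    g : gravitational acceleration, m/s^2
    H_v : latent heat of vaporisation of water, J/kg
    R_sd : specific gas constant of dry air, J/(kg K)
    epsilon : ratio of gas constants dry air / water vapour, dimensionless
    C_pd : specific heat of dry air at constant pressure, J/(kg K)
    p0 : reference sea-level pressure, Pa
    """

    g: float = 9.8076
    H_v: float = 2_501_000.0
    R_sd: float = 287.0
    epsilon: float = 0.622
    C_pd: float = 1005.0
    p0: float = 101_325.0

    def __post_init__(self) -> None:
        for name in ("g", "H_v", "R_sd", "epsilon", "C_pd", "p0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"constant {name} must be positive")
        if not self.epsilon < 1:
            raise ValueError("epsilon must be < 1")

    @property
    def dry_lapse_c_per_km(self) -> float:
        """Dry adiabatic limit g / C_pd in °C per km."""
        return self.g / self.C_pd * 1000.0


DEFAULT_CONSTANTS = ThermoConstants()


@dataclass(frozen=True)
class MoistAirState:
    """Temperature, vapour pressure and air pressure of a moist air parcel."""

    T: float  # K
    e: float  # Pa
    p: float  # Pa

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if not (0 <= self.e < self.p):
            raise ValueError("vapour pressure must satisfy 0 <= e < p")

    @property
    def gamma(self) -> float:
        return mixing_ratio(self.e, self.p)


def barometric_pressure(elevation, T, constants: ThermoConstants = DEFAULT_CONSTANTS):
    """Air pressure at ``elevation`` (m) from the isothermal barometric formula.

    p = p0 * exp(-g h / (R_sd T)) with the location's own mean annual
    temperature T (K).
    """
    T = np.asarray(T, dtype=float)
    if np.any(T[np.isfinite(T)] <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    h = np.asarray(elevation, dtype=float)
    p = constants.p0 * np.exp(-constants.g * h / (constants.R_sd * T))
    return p if p.ndim else float(p)


def mixing_ratio(e, p, constants: ThermoConstants = DEFAULT_CONSTANTS):
    """Mixing ratio gamma = epsilon e / (p - e), kg vapour per kg dry air."""
    scalar = np.ndim(e) == 0 and np.ndim(p) == 0
    e, p = np.broadcast_arrays(np.asarray(e, float), np.asarray(p, float))
    finite = np.isfinite(e) & np.isfinite(p)
    if np.any(e[finite] < 0):
        raise ValueError("vapour pressure must be non-negative")
    if np.any(e[finite] >= p[finite]):
        raise ValueError("vapour pressure must be below air pressure (e < p)")
    g = constants.epsilon * e / (p - e)
    return float(g) if scalar else g


def malrt(T, e, p, constants: ThermoConstants = DEFAULT_CONSTANTS):
    """Moist adiabatic lapse rate in °C per km.

    Parameters are temperature T (K), water vapour pressure e (Pa) and air
    pressure p (Pa); scalars or broadcastable arrays.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T[np.isfinite(T)] <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    gamma = mixing_ratio(e, p, constants)
    c = constants
    numerator = 1.0 + c.H_v * gamma / (c.R_sd * T)
    denominator = c.C_pd + c.H_v**2 * gamma * c.epsilon / (c.R_sd * T**2)
    lapse = c.g * numerator / denominator * 1000.0  # K/m -> °C/km
    return lapse if lapse.ndim else float(lapse)


def saturation_vapour_pressure(T):
    """Saturation vapour pressure over water (Pa), Magnus approximation.

    e_s = 611.2 * exp(17.67 (T - 273.15) / ((T - 273.15) + 243.5)),
    valid for T in 180-340 K.  Used to derive vapour pressure from relative
    humidity when no direct vapour-pressure field is available.
    """
    T = np.asarray(T, dtype=float)
    finite = np.isfinite(T)
    if np.any((T[finite] < 180.0) | (T[finite] > 340.0)):
        raise ValueError("temperature outside the valid 180-340 K range")
    tc = T - 273.15
    es = 611.2 * np.exp(17.67 * tc / (tc + 243.5))
    return es if es.ndim else float(es)


def malrt_grid(
    climatology: DecadalClimatology,
    elevation: Grid2D,
    constants: ThermoConstants = DEFAULT_CONSTANTS,
) -> Grid2D:
    """Per-cell moist adiabatic lapse rate (°C/km) for a decadal climatology.

    Temperature is taken in °C (converted to Kelvin), vapour pressure in hPa
    (converted to Pa); air pressure comes from the barometric formula at the
    cell's mean elevation and temperature.  Nodata propagates cell-wise.
    """
    t_grid = climatology.temperature
    v_grid = climatology.vapour_pressure
    t_grid.require_same_geometry(elevation)

    T = t_grid.values + 273.15
    e = v_grid.values * 100.0  # hPa -> Pa
    valid = np.isfinite(T) & np.isfinite(e) & np.isfinite(elevation.values)

    out = np.full(t_grid.shape, np.nan)
    if np.any(valid):
        p = barometric_pressure(elevation.values[valid], T[valid], constants)
        out[valid] = malrt(T[valid], e[valid], p, constants)
    return t_grid.like(out, units="°C/km")
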