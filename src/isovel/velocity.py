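"""Vertical isotherm-shift velocities from warming rates and lapse rates.

Under a surface warming rate of ``r`` °C/yr and a lapse rate of ``L`` °C/km,
an isotherm moves upslope at ``v = 1000 r / L`` metres per year.  With the
literature's constant 5.5 °C/km, 1 °C of warming displaces isotherms by
about 181.8 m.  Negative lapse rates (inversions) yield downslope
(negative) velocities; near-zero lapse rates yield arbitrarily large finite
velocities and are left in place here — masking them is the exposure
module's job.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import DecadalClimatology, Grid2D

__all__ = [
    "VelocityMap",
    "warming_rate",
    "vertical_velocity",
    "constant_lrt_velocity",
    "signed_log_rescale",
    "signed_log_unscale",
    "normalize",
]


@dataclass
class VelocityMap:
    """A signed vertical-velocity field (m/yr) with its provenance."""

    velocity: Grid2D
    method: str  # "constant" | "malrt" | "slrt"
    warming_rate: Grid2D
    lapse_used: Grid2D

    def __post_init__(self) -> None:
        if self.method not in ("constant", "malrt", "slrt"):
            raise ValueError(f"unknown velocity method: {self.method}")
        self.velocity.require_same_geometry(self.warming_rate)
        self.velocity.require_same_geometry(self.lapse_used)


def warming_rate(
    early: DecadalClimatology, late: DecadalClimatology, years: float = 40.0
) -> Grid2D:
    """Per-cell warming rate (°C/yr): (late decadal mean - early) / years."""
    if not years > 0:
        raise ValueError("years must be positive")
    early.temperature.require_same_geometry(late.temperature)
    rate = (late.temperature.values - early.temperature.values) / years
    return early.temperature.like(rate, units="°C/yr")


def vertical_velocity(rate: Grid2D, lapse: Grid2D, method: str) -> VelocityMap:
    """Velocity map v = 1000 * rate / lapse (m/yr), signed.

    Cells with exactly zero lapse become nodata (counted in a warning);
    nodata in either input propagates.
    """
    rate.require_same_geometry(lapse)
    lp = lapse.values
    zero = np.isfinite(lp) & (lp == 0.0)
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} cells with zero lapse rate set to nodata",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        v = 1000.0 * rate.values / lp
    v = np.where(zero, np.nan, v)
    return VelocityMap(
        velocity=rate.like(v, units="m/yr"),
        method=method,
        warming_rate=rate,
        lapse_used=lapse,
    )


def constant_lrt_velocity(rate: Grid2D, lrt_constant: float = 5.5) -> VelocityMap:
    """Control velocity map under a spatially constant lapse rate."""
    if lrt_constant == 0:
        raise ValueError("constant lapse rate must be nonzero")
    lapse = rate.like(np.full(rate.shape, float(lrt_constant)), units="°C/km")
    # keep the lapse defined only where the rate is, so nodata matches
    lapse.values[~np.isfinite(rate.values)] = np.nan
    return vertical_velocity(rate, lapse, method="constant")


def signed_log_rescale(x):
    """Sign-preserving log rescale sign(x) * log10(|x| + 1).

    Odd, monotone, and zero at zero; used to display heavy-tailed velocity
    distributions without losing the shift direction.
    """
    x = np.asarray(x, dtype=float)
    y = np.sign(x) * np.log10(np.abs(x) + 1.0)
    return y if y.ndim else float(y)


def signed_log_unscale(y):
    """Inverse of :func:`signed_log_rescale`: sign(y) * (10**|y| - 1)."""
    y = np.asarray(y, dtype=float)
    x = np.sign(y) * (10.0 ** np.abs(y) - 1.0)
    return x if x.ndim else float(x)


def normalize(grid: Grid2D, method: str = "zscore") -> Grid2D:
    """Per-map normalisation for display: z-score (default) or rank in [0, 1]."""
    vals = grid.values
    finite = np.isfinite(vals)
    out = np.full(grid.shape, np.nan)
    if method == "zscore":
        mu = np.nanmean(vals)
        sd = np.nanstd(vals)
        out[finite] = 0.0 if sd == 0 else (vals[finite] - mu) / sd
    elif method == "rank":
        from scipy.stats import rankdata

        n = finite.sum()
        if n:
            out[finite] = (rankdata(vals[finite]) - 1) / max(n - 1, 1)
    else:
        raise ValueError(f"unknown normalisation: {method}")
    return grid.like(out, units="normalized")
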