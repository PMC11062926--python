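"""Consensus exposure maps: mountain cells with the highest isotherm velocities.

High-exposure cells are those whose vertical velocity exceeds the
``q``-quantile (default 80th percentile) of finite velocities under the
terrain-transect (SLRT) method, the thermodynamic (MALRT) method, or both.
Because lapse rates close to zero produce arbitrarily large velocities, a
small fraction of near-zero-lapse cells can be masked beforehand.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid2D
from .velocity import VelocityMap

__all__ = [
    "ThreatMap",
    "NOT_THREATENED",
    "THREATENED_ONE",
    "THREATENED_BOTH",
    "remove_near_zero_lapse",
    "consensus_threat",
]

NOT_THREATENED = 0
THREATENED_ONE = 1
THREATENED_BOTH = 2


@dataclass
class ThreatMap:
    """Categorical exposure raster plus the thresholds that generated it."""

    flags: Grid2D  # 0 = not, 1 = one method, 2 = both methods
    quantile_used: float
    mode: str  # "union" | "intersection"
    thresholds: dict  # method -> velocity cutoff (m/yr)

    def flagged_mask(self) -> np.ndarray:
        """Boolean mask of cells flagged under this map's mode."""
        f = self.flags.values
        if self.mode == "union":
            return np.isfinite(f) & (f >= THREATENED_ONE)
        return np.isfinite(f) & (f == THREATENED_BOTH)

    def flagged_fraction(self) -> float:
        """Flagged share of finite cells."""
        finite = np.isfinite(self.flags.values)
        n = int(finite.sum())
        return float(self.flagged_mask().sum()) / n if n else float("nan")

    def summary(self) -> pd.DataFrame:
        rows = [
            {"quantity": f"threshold_{m}", "value": t}
            for m, t in sorted(self.thresholds.items())
        ]
        rows.append({"quantity": "flagged_fraction", "value": self.flagged_fraction()})
        rows.append({"quantity": "quantile", "value": self.quantile_used})
        return pd.DataFrame(rows)


def remove_near_zero_lapse(vmap: VelocityMap, fraction: float = 0.01) -> VelocityMap:
    """Mask the cells whose |lapse| is in the lowest ``fraction`` of the map.

    The ``floor(fraction * n_finite)`` cells with the smallest absolute
    lapse rate are set to nodata (ties broken by scan order), removing the
    near-zero lapse values that blow up the velocity quotient.
    """
    if not (0 <= fraction < 0.5):
        raise ValueError("fraction must lie in [0, 0.5)")
    lapse = vmap.lapse_used.values
    finite = np.flatnonzero(np.isfinite(lapse.ravel()) & np.isfinite(vmap.velocity.values.ravel()))
    k = int(np.floor(fraction * len(finite)))
    vel = vmap.velocity.values.copy()
    lap = lapse.copy()
    if k > 0:
        absl = np.abs(lapse.ravel()[finite])
        drop = finite[np.argsort(absl, kind="stable")[:k]]
        r, c = np.unravel_index(drop, lapse.shape)
        vel[r, c] = np.nan
        lap[r, c] = np.nan
    return VelocityMap(
        velocity=vmap.velocity.like(vel),
        method=vmap.method,
        warming_rate=vmap.warming_rate,
        lapse_used=vmap.lapse_used.like(lap),
    )


def consensus_threat(
    v_malrt: VelocityMap,
    v_slrt: VelocityMap,
    q: float = 0.8,
    mode: str = "union",
    use_absolute: bool = False,
) -> ThreatMap:
    """Flag cells whose velocity exceeds the per-method ``q``-quantile.

    The threshold of each method is the linear-interpolation ``q``-quantile
    of its own finite velocities.  In ``union`` mode a cell is flagged when
    it exceeds either threshold; in ``intersection`` mode only when it
    exceeds both.  The category raster always records whether one or both
    methods fired.
    """
    if not (0 < q < 1):
        raise ValueError("quantile q must lie in (0, 1)")
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown consensus mode: {mode}")
    v_malrt.velocity.require_same_geometry(v_slrt.velocity)

    vm = v_malrt.velocity.values
    vs = v_slrt.velocity.values
    if use_absolute:
        vm, vs = np.abs(vm), np.abs(vs)

    thr_m = float(np.nanquantile(vm, q))
    thr_s = float(np.nanquantile(vs, q))
    hit_m = np.isfinite(vm) & (vm > thr_m)
    hit_s = np.isfinite(vs) & (vs > thr_s)

    flags = np.full(vm.shape, np.nan)
    finite = np.isfinite(vm) | np.isfinite(vs)
    flags[finite] = NOT_THREATENED
    flags[hit_m ^ hit_s] = THREATENED_ONE
    flags[hit_m & hit_s] = THREATENED_BOTH

    return ThreatMap(
        flags=v_malrt.velocity.like(flags, units="category"),
        quantile_used=q,
        mode=mode,
        thresholds={"malrt": thr_m, "slrt": thr_s},
    )
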