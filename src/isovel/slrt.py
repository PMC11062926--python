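"""Satellite-style lapse rate (SLRT) from terrain transects.

The lapse rate of a 0.5° mountain cell is estimated empirically: regional
peaks and foothills are located in a 1.5° x 1.5° window of the fine (0.05°)
DEM centred on the cell, straight transects join each peak to its nearest
foothill (and vice versa), temperature is regressed on elevation along every
fine cell the transect touches, and the significant slopes intersecting the
focal cell are aggregated (median when more than ``median_threshold``
transects intersect, mean otherwise).

The stored SLRT is ``-1000 * beta`` (°C per km), so positive values mean
temperature falls with elevation; negative values are inversions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .grids import Grid2D

__all__ = [
    "TerrainFeature",
    "Transect",
    "detect_features",
    "build_transects",
    "supercover_cells",
    "fit_transect",
    "slrt_map",
]

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class TerrainFeature:
    """A regional peak or foothill of the fine DEM."""

    kind: str  # "peak" | "foothill"
    row: int
    col: int
    elevation: float
    prominence: float = float("inf")


@dataclass
class Transect:
    """A straight elevational path with its temperature-elevation fit."""

    cells: list  # [(row, col), ...] fine-grid indices
    elevations: np.ndarray = field(default=None)
    temperatures: np.ndarray = field(default=None)
    slope_beta: float = float("nan")  # °C per metre
    r_squared: float = float("nan")
    p_value: float = float("nan")
    n: int = 0

    @property
    def slrt(self) -> float:
        """Lapse rate °C/km, positive when temperature falls with height."""
        return -1000.0 * self.slope_beta


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> int:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri
        return ri


def _prominent_maxima(values: np.ndarray, prominence_min: float) -> list[tuple[int, int, float, float]]:
    """Local maxima with topographic prominence >= prominence_min.

    Cells are flooded from the top down with a union--find over the
    already-processed cells; when two summit components merge, the lower
    summit's prominence is its height above the merge level.  Equal-valued
    plateau cells collapse to the lowest row-major representative.  The
    window's highest summit gets prominence relative to the window minimum.
    """
    nr, nc = values.shape
    finite = np.isfinite(values)
    if not finite.any():
        return []
    order = sorted(
        (int(i) for i in np.flatnonzero(finite.ravel())),
        key=lambda i: (-values.ravel()[i], i),
    )
    flat = values.ravel()
    uf = _UnionFind(nr * nc)
    processed = np.zeros(nr * nc, dtype=bool)
    comp_peak: dict[int, int] = {}  # root -> flat index of summit
    results: dict[int, float] = {}  # summit flat index -> prominence
    vmin = float(np.nanmin(values))

    for idx in order:
        r, c = divmod(idx, nc)
        v = flat[idx]
        neigh_roots = []
        for dr, dc in _NEIGHBORS8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc:
                j = rr * nc + cc
                if processed[j]:
                    root = uf.find(j)
                    if root not in neigh_roots:
                        neigh_roots.append(root)
        processed[idx] = True
        if not neigh_roots:
            # new summit component
            uf.parent[idx] = idx
            comp_peak[idx] = idx
            continue
        # attach to the first component, then merge the rest at level v
        neigh_roots.sort(key=lambda root: (-flat[comp_peak[root]], comp_peak[root]))
        main = neigh_roots[0]
        uf.parent[idx] = main
        for other in neigh_roots[1:]:
            dying_peak = comp_peak[other]
            results[dying_peak] = flat[dying_peak] - v
            surv = uf.union(main, other)
            comp_peak[surv] = comp_peak[main]
            main = surv
    for peak in {comp_peak[uf.find(k)] for k in comp_peak}:
        results.setdefault(peak, flat[peak] - vmin)

    out = []
    for peak, prom in sorted(results.items()):
        if prom >= prominence_min and prom > 0:
            r, c = divmod(peak, nc)
            out.append((r, c, float(flat[peak]), float(prom)))
    return out


def detect_features(dem_window: Grid2D | np.ndarray, prominence_min: float = 100.0) -> list[TerrainFeature]:
    """Find regional peaks and foothills in a DEM window.

    Peaks are local maxima of the 8-neighbourhood with topographic
    prominence at least ``prominence_min`` metres; foothills are local
    minima with an equivalent drop.  An all-nodata window yields no
    features.
    """
    values = dem_window.values if isinstance(dem_window, Grid2D) else np.asarray(dem_window, float)
    features: list[TerrainFeature] = []
    for r, c, elev, prom in _prominent_maxima(values, prominence_min):
        features.append(TerrainFeature("peak", r, c, elev, prom))
    for r, c, neg, prom in _prominent_maxima(-values, prominence_min):
        features.append(TerrainFeature("foothill", r, c, -neg, prom))
    return features


# ---------------------------------------------------------------------------
# transect construction
# ---------------------------------------------------------------------------

def supercover_cells(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """All grid cells touched by the segment joining two cell centres.

    Every cell whose (closed) footprint intersects the segment is included,
    even when the segment only grazes a corner.  Exact integer arithmetic:
    coordinates are doubled so cell edges fall on odd integers.
    """
    # scaled coordinates: centre of (r, c) -> (2c, 2r); cell spans +/-1
    ax, ay = 2 * c0, 2 * r0
    bx, by = 2 * c1, 2 * r1
    dx, dy = bx - ax, by - ay
    cells = []
    for r in range(min(r0, r1), max(r0, r1) + 1):
        for c in range(min(c0, c1), max(c0, c1) + 1):
            x_lo, x_hi = 2 * c - 1, 2 * c + 1
            y_lo, y_hi = 2 * r - 1, 2 * r + 1
            # bbox overlap (closed)
            if max(ax, bx) < x_lo or min(ax, bx) > x_hi:
                continue
            if max(ay, by) < y_lo or min(ay, by) > y_hi:
                continue
            # all four rectangle corners strictly on one side of the line?
            sides = [
                dx * (y - ay) - dy * (x - ax)
                for x in (x_lo, x_hi)
                for y in (y_lo, y_hi)
            ]
            if all(s > 0 for s in sides) or all(s < 0 for s in sides):
                continue
            cells.append((r, c))
    return cells


def build_transects(features: list[TerrainFeature]) -> list[Transect]:
    """Join each peak to its nearest foothill and each foothill to its
    nearest peak; duplicate pairs are kept once.

    Distance is planar grid distance between cell centres; ties break toward
    the candidate with the lowest row-major index.  Paths are supercover
    rasterisations, so every touched cell belongs to the transect.
    """
    peaks = [f for f in features if f.kind == "peak"]
    foothills = [f for f in features if f.kind == "foothill"]
    if not peaks or not foothills:
        return []

    def nearest(src: TerrainFeature, candidates: list[TerrainFeature]) -> TerrainFeature:
        return min(
            candidates,
            key=lambda f: (
                (f.row - src.row) ** 2 + (f.col - src.col) ** 2,
                f.row * 10**9 + f.col,
            ),
        )

    pairs: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    ordered: list[tuple[TerrainFeature, TerrainFeature]] = []
    for p in peaks:
        f = nearest(p, foothills)
        key = ((p.row, p.col), (f.row, f.col))
        if key not in pairs:
            pairs.add(key)
            ordered.append((p, f))
    for f in foothills:
        p = nearest(f, peaks)
        key = ((p.row, p.col), (f.row, f.col))
        if key not in pairs:
            pairs.add(key)
            ordered.append((p, f))

    return [
        Transect(cells=supercover_cells(p.row, p.col, f.row, f.col))
        for p, f in ordered
    ]


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def fit_transect(elevations, temperatures):
    """OLS of temperature on elevation: (slope_beta, r_squared, p_value, n).

    Returns None (transect invalid) when fewer than three finite pairs
    remain or the elevations have no variance.  The p-value is the
    two-tailed t test of the slope with n - 2 degrees of freedom.
    """
    z = np.asarray(elevations, dtype=float)
    t = np.asarray(temperatures, dtype=float)
    ok = np.isfinite(z) & np.isfinite(t)
    z, t = z[ok], t[ok]
    n = len(z)
    if n < 3 or np.ptp(z) == 0:
        return None
    res = stats.linregress(z, t)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    p_val = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return float(res.slope), r2, p_val, n


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

def aggregate_betas(betas, median_threshold: int = 10, always_median: bool = False) -> float:
    """Combine retained transect slopes for one coarse cell.

    The median is used when more than ``median_threshold`` transects
    intersect the cell (robust against transect-count extremes), the mean
    otherwise.
    """
    if len(betas) == 0:
        return float("nan")
    if always_median or len(betas) > median_threshold:
        return float(np.median(betas))
    return float(np.mean(betas))


def slrt_map(
    fine_temperature: Grid2D,
    fine_dem: Grid2D,
    coarse_geometry: Grid2D,
    r2_min: float = 0.5,
    p_max: float = 0.05,
    median_threshold: int = 10,
    prominence_min: float = 100.0,
    always_median: bool = False,
    return_table: bool = False,
):
    """Moving-window SLRT over a coarse grid.

    For every coarse cell, transects are built in the surrounding 3x3-cell
    window of the fine DEM (cropped at grid edges), fitted on the fine
    temperature field, filtered at ``r_squared >= r2_min`` and
    ``p <= p_max``, and the slopes of transects intersecting the focal
    coarse cell are aggregated: the median when their count exceeds
    ``median_threshold`` (or ``always_median``), the mean otherwise.

    Returns (slrt_grid, transect_count_grid) in °C/km, plus a per-transect
    DataFrame when ``return_table``.
    """
    fine_temperature.require_same_geometry(fine_dem)
    factor = coarse_geometry.resolution / fine_dem.resolution
    if abs(factor - round(factor)) > 1e-6:
        raise ValueError("coarse resolution must be an integer multiple of fine")
    factor = int(round(factor))

    nr_c, nc_c = coarse_geometry.shape
    nr_f, nc_f = fine_dem.shape
    slrt_vals = np.full((nr_c, nc_c), np.nan)
    counts = np.zeros((nr_c, nc_c), dtype=float)
    rows = []

    dem = fine_dem.values
    temp = fine_temperature.values
    for R in range(nr_c):
        for C in range(nc_c):
            r_lo = max((R - 1) * factor, 0)
            r_hi = min((R + 2) * factor, nr_f)
            c_lo = max((C - 1) * factor, 0)
            c_hi = min((C + 2) * factor, nc_f)
            window = dem[r_lo:r_hi, c_lo:c_hi]
            features = detect_features(window, prominence_min)
            betas = []
            for tr in build_transects(features):
                gcells = [(r + r_lo, c + c_lo) for r, c in tr.cells]
                # does the transect touch the focal coarse cell?
                touches = any(
                    R * factor <= r < (R + 1) * factor
                    and C * factor <= c < (C + 1) * factor
                    for r, c in gcells
                )
                if not touches:
                    continue
                z = np.array([dem[r, c] for r, c in gcells])
                tt = np.array([temp[r, c] for r, c in gcells])
                fit = fit_transect(z, tt)
                if fit is None:
                    continue
                beta, r2, p, n = fit
                if r2 >= r2_min and p <= p_max:
                    betas.append(beta)
                    if return_table:
                        rows.append(
                            {
                                "coarse_row": R,
                                "coarse_col": C,
                                "peak_row": gcells[0][0],
                                "peak_col": gcells[0][1],
                                "foothill_row": gcells[-1][0],
                                "foothill_col": gcells[-1][1],
                                "beta": beta,
                                "r_squared": r2,
                                "p_value": p,
                                "n": n,
                            }
                        )
            counts[R, C] = len(betas)
            if betas:
                agg = aggregate_betas(betas, median_threshold, always_median)
                slrt_vals[R, C] = -1000.0 * agg

    slrt_grid = coarse_geometry.like(slrt_vals, units="°C/km")
    count_grid = coarse_geometry.like(counts, units="count")
    if return_table:
        table = pd.DataFrame(
            rows,
            columns=[
                "coarse_row", "coarse_col", "peak_row", "peak_col",
                "foothill_row", "foothill_col", "beta", "r_squared",
                "p_value", "n",
            ],
        )
        return slrt_grid, count_grid, table
    return slrt_grid, count_grid
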