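"""Velocity summaries and regression on the elevation-latitude plane.

The map of vertical velocities is re-binned into a plane whose axes are
elevation (default 250-m bins anchored at 0 m) and latitude (default 2°
bins anchored at the equator); per plane cell, the mean, standard deviation
and sample size of the source velocities are reported.  A multivariate OLS
(elevation x |latitude| x hemisphere, with all interactions) and a one-way
ANOVA with Tukey HSD post-hoc comparisons support the mainland/island and
hemispheric contrasts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .grids import Grid2D
from .velocity import VelocityMap

__all__ = [
    "bin_elevation_latitude",
    "cell_table",
    "fit_velocity_regression",
    "compare_groups",
]


def bin_elevation_latitude(
    vmap: VelocityMap,
    elevation: Grid2D,
    elev_width: float = 250.0,
    lat_width: float = 2.0,
) -> pd.DataFrame:
    """Group velocities into (elevation, latitude) plane cells.

    Bins are half-open ``[low, high)``, anchored at 0 m and the equator.
    Returns a DataFrame with columns elev_bin_low, lat_bin_low,
    mean_velocity, sd_velocity (NaN when n < 2) and n, sorted by bin.
    """
    vmap.velocity.require_same_geometry(elevation)
    v = vmap.velocity.values
    z = elevation.values
    lat = np.broadcast_to(vmap.velocity.lats()[:, None], v.shape)
    ok = np.isfinite(v) & np.isfinite(z)
    if not ok.any():
        return pd.DataFrame(
            columns=["elev_bin_low", "lat_bin_low", "mean_velocity", "sd_velocity", "n"]
        )
    df = pd.DataFrame(
        {
            "elev_bin_low": np.floor(z[ok] / elev_width) * elev_width,
            "lat_bin_low": np.floor(lat[ok] / lat_width) * lat_width,
            "v": v[ok],
        }
    )
    out = (
        df.groupby(["elev_bin_low", "lat_bin_low"], sort=True)["v"]
        .agg(mean_velocity="mean", sd_velocity="std", n="size")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out


def cell_table(
    vmap: VelocityMap,
    elevation: Grid2D,
    island_mask: Grid2D | None = None,
) -> pd.DataFrame:
    """Flatten a velocity map into a per-cell analysis table.

    Columns: velocity (m/yr), elevation_km, abs_lat (degrees), hemisphere
    ("N"/"S", cells centred exactly on the equator count as Northern) and,
    when ``island_mask`` is given, a boolean ``island`` column.
    """
    vmap.velocity.require_same_geometry(elevation)
    v = vmap.velocity.values
    z = elevation.values
    lat = np.broadcast_to(vmap.velocity.lats()[:, None], v.shape)
    ok = np.isfinite(v) & np.isfinite(z)
    df = pd.DataFrame(
        {
            "velocity": v[ok],
            "elevation_km": z[ok] / 1000.0,
            "abs_lat": np.abs(lat[ok]),
            "hemisphere": np.where(lat[ok] >= 0, "N", "S"),
        }
    )
    if island_mask is not None:
        vmap.velocity.require_same_geometry(island_mask)
        df["island"] = island_mask.values[ok] > 0
    return df


def fit_velocity_regression(cells: pd.DataFrame) -> pd.DataFrame:
    """OLS of velocity on elevation, |latitude| and hemisphere.

    The design holds the intercept, the three main effects (hemisphere as a
    factor with Northern as reference), all two-way interactions and the
    three-way interaction.  Returns the coefficient table (coef, se, t,
    p_value) with the residual degrees of freedom in ``df_resid``.
    """
    required = {"velocity", "elevation_km", "abs_lat", "hemisphere"}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    for hemi in cells["hemisphere"].unique():
        if (cells["hemisphere"] == hemi).sum() < 2:
            raise ValueError(f"hemisphere {hemi} has fewer than 2 observations")

    south = (cells["hemisphere"] == "S").astype(float).to_numpy()
    elev = cells["elevation_km"].to_numpy(float)
    alat = cells["abs_lat"].to_numpy(float)
    X = pd.DataFrame(
        {
            "Intercept": np.ones(len(cells)),
            "elevation_km": elev,
            "abs_lat": alat,
            "hemisphere_S": south,
            "elevation_km:abs_lat": elev * alat,
            "elevation_km:hemisphere_S": elev * south,
            "abs_lat:hemisphere_S": alat * south,
            "elevation_km:abs_lat:hemisphere_S": elev * alat * south,
        }
    )
    # keep only estimable columns in a single-hemisphere design
    if south.max() == south.min():
        X = X[["Intercept", "elevation_km", "abs_lat", "elevation_km:abs_lat"]]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by greedy rank check
        bad = []
        kept: list[str] = []
        for col in X.columns:
            trial = X[kept + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(col)
            else:
                bad.append(col)
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    model = sm.OLS(cells["velocity"].to_numpy(float), X).fit()
    table = pd.DataFrame(
        {
            "term": X.columns,
            "coef": model.params.to_numpy(),
            "se": model.bse.to_numpy(),
            "t": model.tvalues.to_numpy(),
            "p_value": model.pvalues.to_numpy(),
        }
    )
    table["df_resid"] = int(model.df_resid)
    return table


def compare_groups(velocities, labels) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD pairwise comparisons across groups.

    ``velocities`` is a 1-D sequence; ``labels`` assigns each value to a
    group (e.g. N. mainland / N. island / S. mainland / S. island).
    Returns (anova_table, tukey_table).
    """
    v = np.asarray(velocities, dtype=float)
    lab = np.asarray(labels)
    ok = np.isfinite(v)
    v, lab = v[ok], lab[ok]
    groups = [v[lab == g] for g in pd.unique(lab)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")

    f_stat, p = stats.f_oneway(*groups)
    k, n = len(groups), len(v)
    anova = pd.DataFrame(
        [{"F": float(f_stat), "p_value": float(p), "df_between": k - 1, "df_within": n - k}]
    )
    tk = pairwise_tukeyhsd(v, lab)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return anova, tukey
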