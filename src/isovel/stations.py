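"""Station-based lapse rates and validation of the gridded lapse-rate maps.

Weather stations with sufficiently complete monthly records are pooled into
"mountain sites" — 3x3 clusters of coarse grid cells — and the lapse rate
of a site is the (negated, km-scaled) OLS slope of station mean annual
temperature on station elevation.  Site lapse rates then validate the
thermodynamic and terrain-transect maps through two simple linear models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .grids import Grid2D

__all__ = [
    "StationRecord",
    "MountainSite",
    "filter_stations",
    "build_sites",
    "site_lrt",
    "validate_lapse_maps",
    "read_station_csv",
    "write_station_csv",
]

STATION_CSV_COLUMNS = ["id", "lat", "lon", "elevation_m", "year", "month", "tmean_c"]


@dataclass
class StationRecord:
    """One weather station with its monthly temperature series."""

    station_id: str
    lat: float
    lon: float
    elevation: float  # metres
    monthly_temperature: pd.DataFrame  # columns: year, month, tmean_c
    mean_annual_temperature: float = float("nan")  # filled by filter_stations

    def __post_init__(self) -> None:
        t = self.monthly_temperature
        if not {"year", "month", "tmean_c"} <= set(t.columns):
            raise ValueError("monthly table needs year, month, tmean_c columns")
        if t["month"].min() < 1 or t["month"].max() > 12:
            raise ValueError("months must lie in 1..12")
        if t.duplicated(["year", "month"]).any():
            raise ValueError("duplicate (year, month) entries")


@dataclass
class MountainSite:
    """A 3x3 coarse-cell cluster of stations with its lapse-rate estimate."""

    center: tuple[int, int]  # coarse (row, col)
    stations: list = field(default_factory=list)
    lrt: float | None = None  # °C/km, None when undefined

    @property
    def n_stations(self) -> int:
        return len(self.stations)


def filter_stations(
    records: list[StationRecord],
    window: tuple[int, int] = (2011, 2019),
    min_years: int = 8,
    min_months_per_year: int = 10,
) -> list[StationRecord]:
    """Keep stations with enough complete years; compute mean annual T.

    A year qualifies when strictly more than ``min_months_per_year`` months
    are recorded; a station is retained when it has at least ``min_years``
    qualifying years inside the window.  The station's mean annual
    temperature is the mean over qualifying years of the yearly mean.
    """
    lo, hi = window
    out = []
    for rec in records:
        t = rec.monthly_temperature
        t = t[(t["year"] >= lo) & (t["year"] <= hi) & np.isfinite(t["tmean_c"])]
        months_per_year = t.groupby("year")["month"].nunique()
        good_years = months_per_year[months_per_year > min_months_per_year].index
        if len(good_years) < min_years:
            continue
        annual = t[t["year"].isin(good_years)].groupby("year")["tmean_c"].mean()
        out.append(
            StationRecord(
                station_id=rec.station_id,
                lat=rec.lat,
                lon=rec.lon,
                elevation=rec.elevation,
                monthly_temperature=rec.monthly_temperature,
                mean_annual_temperature=float(annual.mean()),
            )
        )
    return out


def build_sites(records: list[StationRecord], coarse_geometry: Grid2D) -> list[MountainSite]:
    """Assemble mountain sites: one per coarse cell with stations in its
    3x3 neighbourhood, deduplicated by identical station sets."""
    cell_of: dict[str, tuple[int, int]] = {}
    for rec in records:
        try:
            cell_of[rec.station_id] = coarse_geometry.index_of(rec.lat, rec.lon)
        except IndexError:
            continue
    sites = []
    seen: set[frozenset] = set()
    nr, nc = coarse_geometry.shape
    occupied = {cell for cell in cell_of.values()}
    for R in range(nr):
        for C in range(nc):
            members = [
                rec
                for rec in records
                if rec.station_id in cell_of
                and abs(cell_of[rec.station_id][0] - R) <= 1
                and abs(cell_of[rec.station_id][1] - C) <= 1
            ]
            if not members or (R, C) not in occupied:
                continue
            key = frozenset(m.station_id for m in members)
            if key in seen:
                continue
            seen.add(key)
            site = MountainSite(center=(R, C), stations=members)
            site.lrt = site_lrt(site)
            sites.append(site)
    return sites


def site_lrt(site: MountainSite) -> float | None:
    """Station-based lapse rate of a site, °C/km.

    OLS of station mean annual temperature on elevation; the lapse rate is
    ``-1000 * slope``.  Undefined (None) with fewer than three stations at
    distinct elevations.
    """
    z = np.array([s.elevation for s in site.stations], dtype=float)
    t = np.array([s.mean_annual_temperature for s in site.stations], dtype=float)
    ok = np.isfinite(z) & np.isfinite(t)
    z, t = z[ok], t[ok]
    if len(z) < 3 or len(np.unique(z)) < 3:
        return None
    res = stats.linregress(z, t)
    return float(-1000.0 * res.slope)


def validate_lapse_maps(
    sites: list[MountainSite],
    malrt_map: Grid2D,
    slrt_map: Grid2D,
    mad_factor: float = 3.0,
) -> pd.DataFrame:
    """Regress station lapse rates on each map's value at the site centre.

    Sites whose station lapse rate deviates from the median by more than
    ``mad_factor`` median absolute deviations are excluded (a reproducible
    stand-in for ad-hoc outlier removal); excluded site centres are listed
    in the ``excluded`` attribute of the returned frame.  One row per map
    with slope, F, df, p_value, r_squared, n.
    """
    rows = [
        (s.center, s.lrt, malrt_map.values[s.center], slrt_map.values[s.center])
        for s in sites
        if s.lrt is not None
    ]
    if not rows:
        raise ValueError("no sites with a defined lapse rate")
    lrts = np.array([r[1] for r in rows], dtype=float)
    med = np.median(lrts)
    mad = np.median(np.abs(lrts - med))
    keep = np.abs(lrts - med) <= mad_factor * mad if mad > 0 else np.ones(len(lrts), bool)
    excluded = [rows[i][0] for i in np.flatnonzero(~keep)]

    out = []
    for name, col in (("malrt", 2), ("slrt", 3)):
        x = np.array([r[col] for r in rows], dtype=float)[keep]
        y = lrts[keep]
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            raise ValueError(f"fewer than 3 usable sites for the {name} model")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        out.append(
            {
                "map": name,
                "slope": float(model.params[1]),
                "F": float(model.fvalue),
                "df_model": int(model.df_model),
                "df_resid": int(model.df_resid),
                "p_value": float(model.f_pvalue),
                "r_squared": float(model.rsquared),
                "n": len(x),
            }
        )
    result = pd.DataFrame(out)
    result.attrs["excluded"] = excluded
    return result


def read_station_csv(path) -> list[StationRecord]:
    """Read a long-format station CSV (id, lat, lon, elevation_m, year,
    month, tmean_c) into StationRecords.

    This is also the place to map network dialects: any table with one row
    per station-month reduces to this schema by renaming columns.
    """
    df = pd.read_csv(path)
    missing = set(STATION_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"station CSV lacks columns: {sorted(missing)}")
    records = []
    for sid, sub in df.groupby("id", sort=True):
        records.append(
            StationRecord(
                station_id=str(sid),
                lat=float(sub["lat"].iloc[0]),
                lon=float(sub["lon"].iloc[0]),
                elevation=float(sub["elevation_m"].iloc[0]),
                monthly_temperature=sub[["year", "month", "tmean_c"]].reset_index(drop=True),
            )
        )
    return records


def write_station_csv(records: list[StationRecord], path) -> None:
    frames = []
    for rec in records:
        t = rec.monthly_temperature.copy()
        t.insert(0, "id", rec.station_id)
        t.insert(1, "lat", rec.lat)
        t.insert(2, "lon", rec.lon)
        t.insert(3, "elevation_m", rec.elevation)
        frames.append(t[STATION_CSV_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
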