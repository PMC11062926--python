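"""Synthetic mountain landscapes, climatologies, station networks and
range-shift records.

Every generator is a pure function of its scenario and seed, and the
outputs carry the statistical structure the analysis assumes: terrain with
controllable peaks, temperature fields that fall off elevation at a known
lapse rate with Gaussian noise, decadal climatology pairs with a prescribed
warming, station networks on a known lapse rate with controllable record
gaps, and range-shift records that lag the local isotherm velocity by a
controllable deficit.  Defaults describe a 3° x 3° mountainous region at
0.05° resolution (60 x 60 cells, 6 x 6 at the 0.5° analysis scale).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import DecadalClimatology, Grid2D
from .stations import StationRecord
from .tracking import TAXON_GROUPS, RangeShiftRecord
from .velocity import VelocityMap

__all__ = ["SyntheticScenario", "make_dem", "make_island_mask",
           "make_temperature_field", "make_decadal_pair", "make_stations",
           "make_range_shifts"]


@dataclass
class SyntheticScenario:
    """Parameters of a synthetic study region.

    The defaults are the package's reference conditions: a 6.5 °C/km true
    lapse rate with 0.05 °C temperature noise, 1 °C of warming over 40
    years, and a 10 hPa sea-level vapour pressure declining with elevation.
    """

    seed: int = 0
    n_rows_fine: int = 60
    n_cols_fine: int = 60
    fine_resolution: float = 0.05  # degrees
    coarse_factor: int = 10  # 0.5° analysis cells
    lat_origin: float = 47.0  # NW cell centre
    lon_origin: float = 8.0
    true_lapse: float = 6.5  # °C/km
    lapse_noise_sd: float = 0.05  # °C
    t0_sea_level: float = 15.0  # °C at z = 0
    lat_gradient: float = 0.0  # °C per degree latitude (sea level)
    warming_per_40yr: float = 1.0  # °C
    vapour_base: float = 10.0  # hPa at sea level
    vapour_scale_height: float = 2500.0  # m
    n_peaks: int = 8
    peak_height_range: tuple = (1500.0, 3000.0)
    peak_sigma_range: tuple = (2.0, 4.0)  # cells
    n_valleys: int = 8
    valley_depth_range: tuple = (250.0, 450.0)
    base_elevation: float = 500.0  # m
    dem_noise_amplitude: float = 10.0  # m, correlated
    island_fraction: float = 0.2
    station_count: int = 25
    station_incomplete_fraction: float = 0.2
    n_range_shifts: int = 210
    tracking_lag: float = 0.0  # m/yr
    shift_noise_sd: float = 1.0  # m/yr
    extent_over_fraction: float = 0.3  # share of studies wider than 1°

    def __post_init__(self) -> None:
        if not (0 < self.true_lapse <= 9.8):
            raise ValueError("true_lapse must lie in (0, 9.8] °C/km")
        if self.n_peaks < 1:
            raise ValueError("need at least one peak")
        if not (0 <= self.island_fraction <= 1):
            raise ValueError("island_fraction must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        """Named deterministic substream of the scenario seed."""
        code = sum((i + 1) * b for i, b in enumerate(stream.encode())) % (2**31)
        return np.random.default_rng(np.random.SeedSequence([self.seed, code]))

    def fine_geometry(self) -> Grid2D:
        return Grid2D(
            values=np.zeros((self.n_rows_fine, self.n_cols_fine)),
            lat_origin=self.lat_origin,
            lon_origin=self.lon_origin,
            resolution=self.fine_resolution,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("peak_height_range", "peak_sigma_range", "valley_depth_range"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticScenario":
        d = dict(d)
        for key in ("peak_height_range", "peak_sigma_range", "valley_depth_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def make_dem(scenario: SyntheticScenario) -> Grid2D:
    """Terrain as seeded Gaussian peaks and valley depressions over a base.

    Feature centres are kept apart (rejection sampling) so each peak
    remains a distinct local maximum and each valley a distinct minimum; a
    low-amplitude spatially correlated noise field roughens the surface
    without adding prominent features.
    """
    rng = scenario.rng("dem")
    nr, nc = scenario.n_rows_fine, scenario.n_cols_fine
    margin = 6
    n_feat = scenario.n_peaks + scenario.n_valleys
    min_sep = max(min(nr, nc) // max(n_feat - 1, 1) + 4, 10)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_feat:
        r = rng.uniform(margin, nr - margin)
        c = rng.uniform(margin, nc - margin)
        attempts += 1
        sep_ok = all(np.hypot(r - r0, c - c0) >= min_sep for r0, c0 in centers)
        if sep_ok or attempts > 2000:
            centers.append((r, c))
    heights = rng.uniform(*scenario.peak_height_range, size=scenario.n_peaks)
    depths = rng.uniform(*scenario.valley_depth_range, size=scenario.n_valleys)
    sigmas = rng.uniform(*scenario.peak_sigma_range, size=n_feat)

    rr, cc = np.mgrid[0:nr, 0:nc]
    z = np.full((nr, nc), scenario.base_elevation)
    amps = np.concatenate([heights, -depths])
    for (r0, c0), h, s in zip(centers, amps, sigmas):
        z = z + h * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2))
    if scenario.dem_noise_amplitude > 0:
        noise = gaussian_filter(rng.standard_normal((nr, nc)), sigma=2.0)
        sd = noise.std()
        if sd > 0:
            z = z + scenario.dem_noise_amplitude * noise / sd
    geom = scenario.fine_geometry()
    return geom.like(z, units="m")


def make_island_mask(scenario: SyntheticScenario, coarse: Grid2D) -> Grid2D:
    """Boolean island attribute per coarse cell (1 = island), with about
    ``island_fraction`` of cells insular, drawn without replacement."""
    rng = scenario.rng("island")
    n = coarse.values.size
    k = int(round(scenario.island_fraction * n))
    mask = np.zeros(n)
    if k:
        mask[rng.choice(n, size=k, replace=False)] = 1.0
    return coarse.like(mask.reshape(coarse.shape), units="bool")


def _sea_level_temperature(scenario: SyntheticScenario, lats: np.ndarray) -> np.ndarray:
    return scenario.t0_sea_level - scenario.lat_gradient * np.abs(lats)


def make_temperature_field(
    dem: Grid2D, scenario: SyntheticScenario, noise_stream: str = "temperature"
) -> Grid2D:
    """Mean annual temperature T = T0(lat) - true_lapse * z / 1000 + noise."""
    rng = scenario.rng(noise_stream)
    t0 = _sea_level_temperature(scenario, dem.lats())[:, None]
    t = t0 - scenario.true_lapse * dem.values / 1000.0
    if scenario.lapse_noise_sd > 0:
        t = t + rng.normal(0.0, scenario.lapse_noise_sd, size=dem.shape)
    return dem.like(t, units="°C")


def _vapour_field(dem: Grid2D, scenario: SyntheticScenario, stream: str) -> Grid2D:
    rng = scenario.rng(stream)
    vap = scenario.vapour_base * np.exp(-dem.values / scenario.vapour_scale_height)
    vap = vap + rng.normal(0.0, 0.1, size=dem.shape)
    return dem.like(np.clip(vap, 0.0, None), units="hPa")


def make_decadal_pair(
    dem: Grid2D,
    scenario: SyntheticScenario,
    warming_field: np.ndarray | None = None,
) -> tuple[DecadalClimatology, DecadalClimatology]:
    """Early and late decadal climatologies separated by the prescribed
    warming (uniform by default, or a supplied per-cell field)."""
    early_t = make_temperature_field(dem, scenario)
    warming = (
        np.full(dem.shape, scenario.warming_per_40yr)
        if warming_field is None
        else np.asarray(warming_field, dtype=float)
    )
    late_t = early_t.like(early_t.values + warming)
    early = DecadalClimatology(
        temperature=early_t,
        vapour_pressure=_vapour_field(dem, scenario, "vapour_early"),
        period_label="early decade",
    )
    late = DecadalClimatology(
        temperature=late_t,
        vapour_pressure=_vapour_field(dem, scenario, "vapour_late"),
        period_label="late decade",
    )
    return early, late


def make_stations(
    dem: Grid2D,
    scenario: SyntheticScenario,
    years: tuple[int, int] = (2011, 2019),
    seasonal_amplitude: float = 8.0,
    monthly_noise_sd: float = 0.3,
) -> list[StationRecord]:
    """Station networks on the synthetic temperature surface.

    Stations sit at seeded fine cells; their monthly series follow the
    local mean annual temperature plus a seasonal cycle and noise.  A
    seeded fraction of stations records only 10 months per year, which the
    completeness filter must reject.
    """
    rng = scenario.rng("stations")
    nr, nc = dem.shape
    idx = rng.choice(nr * nc, size=scenario.station_count, replace=False)
    n_incomplete = int(round(scenario.station_incomplete_fraction * scenario.station_count))
    incomplete = set(range(n_incomplete))  # first k draws are the gappy ones
    t0 = _sea_level_temperature(scenario, dem.lats())[:, None]
    records = []
    year_list = list(range(years[0], years[1] + 1))
    for i, flat in enumerate(idx):
        r, c = divmod(int(flat), nc)
        z = float(dem.values[r, c]) + float(rng.normal(0, 5))
        annual_mean = float(t0[r, 0] - scenario.true_lapse * z / 1000.0)
        rows = []
        for year in year_list:
            months = range(1, 13) if i not in incomplete else range(1, 11)
            for month in months:
                temp = (
                    annual_mean
                    - seasonal_amplitude * np.cos(2 * np.pi * (month - 1) / 12 - np.pi)
                    + rng.normal(0, monthly_noise_sd)
                )
                rows.append({"year": year, "month": month, "tmean_c": temp})
        lat, lon = dem.cell_center(r, c)
        records.append(
            StationRecord(
                station_id=f"SYN{i:04d}",
                lat=lat,
                lon=lon,
                elevation=z,
                monthly_temperature=pd.DataFrame(rows),
            )
        )
    return records


def make_range_shifts(
    velocity_map: VelocityMap, scenario: SyntheticScenario
) -> list[RangeShiftRecord]:
    """Range-shift records lagging the local isotherm velocity.

    Each record sits at a seeded finite cell of the velocity map, its shift
    is the local velocity minus ``tracking_lag`` plus symmetric noise, and
    an ``extent_over_fraction`` share of the studies is given bounding
    boxes wider than 1° (to exercise the extent filter).  Taxon labels
    rotate through the seven groups; region ids split the map into
    quadrants.
    """
    rng = scenario.rng("shifts")
    vgrid = velocity_map.velocity
    finite = np.flatnonzero(np.isfinite(vgrid.values.ravel()))
    if finite.size == 0:
        raise ValueError("velocity map has no finite cells")
    n = scenario.n_range_shifts
    cells = rng.choice(finite, size=n, replace=True)
    n_over = int(round(scenario.extent_over_fraction * n))
    records = []
    mid_r, mid_c = vgrid.n_rows / 2, vgrid.n_cols / 2
    for i, flat in enumerate(cells):
        r, c = divmod(int(flat), vgrid.n_cols)
        lat, lon = vgrid.cell_center(r, c)
        v = float(vgrid.values[r, c])
        shift = v - scenario.tracking_lag + float(
            rng.normal(0, scenario.shift_noise_sd)
        )
        if i < n_over:
            ext = (float(rng.uniform(1.1, 2.0)), float(rng.uniform(0.2, 2.0)))
        else:
            ext = (float(rng.uniform(0.1, 0.9)), float(rng.uniform(0.1, 0.9)))
        region = f"r{int(r >= mid_r) * 2 + int(c >= mid_c)}"
        records.append(
            RangeShiftRecord(
                taxon_group=TAXON_GROUPS[i % len(TAXON_GROUPS)],
                region_id=region,
                centroid_lat=lat,
                centroid_lon=lon,
                extent_deg_x=ext[0],
                extent_deg_y=ext[1],
                shift_velocity=shift,
            )
        )
    return records
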