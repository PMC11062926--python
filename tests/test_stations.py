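import numpy as np
import pandas as pd
import pytest

from isovel.grids import Grid2D
from isovel.stations import (
    MountainSite,
    StationRecord,
    build_sites,
    filter_stations,
    read_station_csv,
    site_lrt,
    validate_lapse_maps,
    write_station_csv,
)


def station(sid="S1", lat=46.75, lon=8.25, elevation=500.0, years=9, months=12,
            temp=10.0):
    rows = [
        {"year": 2011 + y, "month": m, "tmean_c": temp}
        for y in range(years)
        for m in range(1, months + 1)
    ]
    return StationRecord(sid, lat, lon, elevation, pd.DataFrame(rows))


def coarse_geometry(n=6, lat0=47.0, lon0=8.0):
    return Grid2D(values=np.zeros((n, n)), lat_origin=lat0, lon_origin=lon0,
                  resolution=0.5)


class TestFilterStations:
    def test_complete_station_retained(self):
        out = filter_stations([station(years=9, months=12)])
        assert len(out) == 1
        assert out[0].mean_annual_temperature == pytest.approx(10.0)

    def test_ten_months_per_year_rejected(self):
        # "more than 10 months" is strict: 10 does not qualify
        assert filter_stations([station(years=9, months=10)]) == []

    def test_eleven_months_qualify(self):
        assert len(filter_stations([station(years=9, months=11)])) == 1

    def test_seven_good_years_rejected_eight_retained(self):
        assert filter_stations([station(years=7)]) == []
        assert len(filter_stations([station(years=8)])) == 1

    def test_mean_uses_qualifying_years_only(self):
        rows = []
        for y in range(2011, 2020):
            months = 12 if y < 2019 else 3  # last year incomplete
            temp = 10.0 if y < 2019 else 100.0
            rows += [{"year": y, "month": m, "tmean_c": temp}
                     for m in range(1, months + 1)]
        rec = StationRecord("S", 46.75, 8.25, 100.0, pd.DataFrame(rows))
        (out,) = filter_stations([rec])
        assert out.mean_annual_temperature == pytest.approx(10.0)

    def test_random_gap_patterns_match_counting_oracle(self):
        rng = np.random.default_rng(17)
        records = []
        for i in range(30):
            rows = []
            for y in range(2011, 2020):
                got = rng.choice(12, size=rng.integers(6, 13), replace=False)
                rows += [{"year": y, "month": int(m) + 1, "tmean_c": 5.0}
                         for m in got]
            records.append(StationRecord(f"S{i}", 46.75, 8.25, 0.0,
                                         pd.DataFrame(rows)))
        kept = {r.station_id for r in filter_stations(records)}
        for rec in records:
            t = rec.monthly_temperature
            good = sum(
                t[t.year == y]["month"].nunique() > 10 for y in range(2011, 2020)
            )
            assert (rec.station_id in kept) == (good >= 8)


class TestSiteLrt:
    def test_exact_line_recovers_six(self):
        stations = []
        for i, z in enumerate((200.0, 900.0, 1700.0)):
            s = station(f"S{i}", elevation=z)
            s.mean_annual_temperature = 18.0 - 0.006 * z
            stations.append(s)
        site = MountainSite(center=(0, 0), stations=stations)
        assert site_lrt(site) == pytest.approx(6.0)

    def test_two_stations_undefined(self):
        stations = [station("A", elevation=100.0), station("B", elevation=900.0)]
        for s in stations:
            s.mean_annual_temperature = 5.0
        assert site_lrt(MountainSite(center=(0, 0), stations=stations)) is None

    def test_degenerate_elevations_undefined(self):
        stations = [station(f"S{i}", elevation=500.0) for i in range(4)]
        for s in stations:
            s.mean_annual_temperature = 5.0
        assert site_lrt(MountainSite(center=(0, 0), stations=stations)) is None

    def test_noisy_stations_match_normal_equations(self):
        rng = np.random.default_rng(41)
        z = rng.uniform(100, 2500, 5)
        t = 15 - 0.0065 * z + rng.normal(0, 0.2, 5)
        stations = []
        for i in range(5):
            s = station(f"S{i}", elevation=float(z[i]))
            s.mean_annual_temperature = float(t[i])
            stations.append(s)
        zc, tc = z - z.mean(), t - t.mean()
        slope = (zc * tc).sum() / (zc**2).sum()
        assert site_lrt(MountainSite((0, 0), stations)) == pytest.approx(
            -1000 * slope
        )


class TestBuildSites:
    def test_cluster_membership_and_dedup(self):
        geom = coarse_geometry()
        recs = []
        for i, (lat, lon) in enumerate([(47.0, 8.0), (47.0, 8.5), (46.5, 8.0)]):
            s = station(f"S{i}", lat=lat, lon=lon, elevation=100.0 * (i + 1))
            s.mean_annual_temperature = 10.0 - i
            recs.append(s)
        sites = build_sites(recs, geom)
        # all three stations fall inside one 3x3 neighbourhood; identical
        # member sets collapse to a single site
        assert any(s.n_stations == 3 for s in sites)
        keys = [frozenset(m.station_id for m in s.stations) for s in sites]
        assert len(keys) == len(set(keys))


class TestValidation:
    @staticmethod
    def make_sites_from_map(map_grid, noise_sd, rng, n=16):
        sites = []
        nr, nc = map_grid.shape
        cells = rng.choice(nr * nc, size=n, replace=False)
        for flat in cells:
            r, c = divmod(int(flat), nc)
            site = MountainSite(center=(r, c), stations=[])
            site.lrt = float(map_grid.values[r, c] + rng.normal(0, noise_sd))
            sites.append(site)
        return sites

    def test_correlated_lrts_give_significant_positive_slope(self):
        rng = np.random.default_rng(51)
        geom = coarse_geometry(8)
        malrt = geom.like(rng.uniform(4, 9, (8, 8)), "°C/km")
        slrt = geom.like(rng.uniform(4, 9, (8, 8)), "°C/km")
        wins = 0
        reps = 20
        for _ in range(reps):
            sites = self.make_sites_from_map(malrt, 0.3, rng)
            res = validate_lapse_maps(sites, malrt, slrt).set_index("map")
            if (res.loc["malrt", "slope"] > 0) and (res.loc["malrt", "p_value"] < 0.05):
                wins += 1
        assert wins >= 19  # >= 95% of replicates

    def test_uncorrelated_lrts_rarely_significant(self):
        rng = np.random.default_rng(52)
        geom = coarse_geometry(8)
        malrt = geom.like(rng.uniform(4, 9, (8, 8)), "°C/km")
        slrt = geom.like(rng.uniform(4, 9, (8, 8)), "°C/km")
        hits = 0
        reps = 30
        for _ in range(reps):
            sites = []
            nr, nc = malrt.shape
            for flat in rng.choice(nr * nc, size=16, replace=False):
                site = MountainSite(center=divmod(int(flat), nc), stations=[])
                site.lrt = float(rng.uniform(4, 9))
                sites.append(site)
            res = validate_lapse_maps(sites, malrt, slrt).set_index("map")
            hits += int(res.loc["malrt", "p_value"] < 0.05)
        assert hits <= 5  # ~5% type-I rate, Monte-Carlo slack

    def test_gross_outlier_excluded_by_mad_rule(self):
        # deterministic, tightly clustered lapse rates: the MAD rule keeps
        # all genuine sites and drops only the injected gross outlier
        geom = coarse_geometry(8)
        vals = np.linspace(5.5, 7.5, 64).reshape(8, 8)
        malrt = geom.like(vals, "°C/km")
        slrt = geom.like(vals[::-1], "°C/km")
        sites = []
        for i, flat in enumerate(range(0, 64, 4)):
            s = MountainSite(center=divmod(flat, 8), stations=[])
            s.lrt = float(vals.ravel()[flat] + 0.05 * (-1) ** i)
            sites.append(s)
        base = validate_lapse_maps(sites, malrt, slrt).set_index("map")
        assert base.attrs["excluded"] == []
        spoiled = sites + [MountainSite(center=(0, 0), stations=[])]
        spoiled[-1].lrt = 500.0
        res = validate_lapse_maps(spoiled, malrt, slrt).set_index("map")
        assert (0, 0) in res.attrs["excluded"]
        assert res.loc["malrt", "slope"] == pytest.approx(
            base.loc["malrt", "slope"], rel=1e-6
        )

    def test_df_equals_n_minus_two(self):
        rng = np.random.default_rng(54)
        geom = coarse_geometry(8)
        malrt = geom.like(rng.uniform(4, 9, (8, 8)), "°C/km")
        sites = self.make_sites_from_map(malrt, 0.3, rng, n=12)
        res = validate_lapse_maps(sites, malrt, malrt).set_index("map")
        assert res.loc["malrt", "df_resid"] == res.loc["malrt", "n"] - 2

    def test_too_few_sites_error(self):
        geom = coarse_geometry()
        with pytest.raises(ValueError):
            validate_lapse_maps([], geom, geom)


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        recs = [station("A", elevation=120.0), station("B", lat=46.25, elevation=900.0)]
        path = tmp_path / "stations.csv"
        write_station_csv(recs, path)
        back = read_station_csv(path)
        assert [r.station_id for r in back] == ["A", "B"]
        assert back[0].elevation == 120.0
        assert len(back[0].monthly_temperature) == 9 * 12
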