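import numpy as np
import pytest
from scipy import ndimage

from isovel.grids import aggregate
from isovel.slrt import (
    TerrainFeature,
    aggregate_betas,
    build_transects,
    detect_features,
    fit_transect,
    slrt_map,
    supercover_cells,
)
from isovel.synthetic import SyntheticScenario, make_dem, make_temperature_field


def gaussian_bump(n=21, height=1000.0, sigma=4.0):
    rr, cc = np.mgrid[0:n, 0:n]
    mid = n // 2
    return height * np.exp(-((rr - mid) ** 2 + (cc - mid) ** 2) / (2 * sigma**2))


def brute_force_peaks(values, prominence_min):
    """Independent prominence oracle: descending threshold flood with
    scipy.ndimage labelling."""
    nr, nc = values.shape
    peaks = []
    levels = np.unique(values)[::-1]
    for r in range(nr):
        for c in range(nc):
            h = values[r, c]
            neigh = values[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
            if h < neigh.max():
                continue
            if np.sum(neigh == h) > 1:
                # plateau member: only the lowest row-major index represents it
                plateau = np.argwhere(values == h)
                rep = min((rr * nc + cc) for rr, cc in plateau
                          if abs(rr - r) <= 1 and abs(cc - c) <= 1)
                if rep != r * nc + c:
                    continue
            prom = h - values.min()
            for lev in levels[levels < h]:
                lab, _ = ndimage.label(values >= lev, structure=np.ones((3, 3)))
                comp = lab == lab[r, c]
                if values[comp].max() > h:
                    prom = h - lev
                    break
            if prom >= prominence_min and prom > 0:
                peaks.append((r, c))
    return sorted(peaks)


class TestDetectFeatures:
    def test_single_bump_one_peak(self):
        z = gaussian_bump()
        feats = detect_features(z, prominence_min=100.0)
        peaks = [f for f in feats if f.kind == "peak"]
        assert len(peaks) == 1 and (peaks[0].row, peaks[0].col) == (10, 10)
        foothills = [f for f in feats if f.kind == "foothill"]
        assert foothills, "rim minima expected around a unimodal bump"
        assert all(f.row in (0, 20) or f.col in (0, 20) for f in foothills)

    def test_constant_surface_has_no_features(self):
        assert detect_features(np.full((9, 9), 5.0), prominence_min=0.0) == []

    def test_all_nodata_window_empty(self):
        assert detect_features(np.full((5, 5), np.nan), 10.0) == []

    def test_two_bumps_with_saddle(self):
        rr, cc = np.mgrid[0:20, 0:40]
        z = 1000 * np.exp(-((rr - 10) ** 2 + (cc - 10) ** 2) / 18.0)
        z += 800 * np.exp(-((rr - 10) ** 2 + (cc - 30) ** 2) / 18.0)
        feats = detect_features(z, prominence_min=100.0)
        peaks = sorted((f.row, f.col) for f in feats if f.kind == "peak")
        assert peaks == [(10, 10), (10, 30)]

    def test_prominence_against_flood_oracle(self):
        rng = np.random.default_rng(11)
        z = ndimage.gaussian_filter(rng.normal(0, 300, (14, 14)), 1.2)
        for prom_min in (50.0, 150.0):
            mine = sorted(
                (f.row, f.col) for f in detect_features(z, prom_min)
                if f.kind == "peak"
            )
            assert mine == brute_force_peaks(z, prom_min)

    def test_small_prominence_filtered(self):
        z = gaussian_bump(height=80.0)
        assert [f for f in detect_features(z, 100.0) if f.kind == "peak"] == []


class TestSupercover:
    def test_horizontal_line(self):
        assert supercover_cells(2, 0, 2, 5) == [(2, c) for c in range(6)]

    def test_single_cell(self):
        assert supercover_cells(3, 3, 3, 3) == [(3, 3)]

    @pytest.mark.parametrize(
        "ends", [(0, 0, 2, 3), (0, 0, 3, 2), (5, 1, 0, 4), (0, 0, 4, 4), (2, 7, 6, 0)]
    )
    def test_matches_shapely_intersection_oracle(self, ends):
        from shapely.geometry import LineString, box

        r0, c0, r1, c1 = ends
        seg = LineString([(c0, r0), (c1, r1)])
        expect = sorted(
            (r, c)
            for r in range(min(r0, r1), max(r0, r1) + 1)
            for c in range(min(c0, c1), max(c0, c1) + 1)
            if seg.intersects(box(c - 0.5, r - 0.5, c + 0.5, r + 0.5))
        )
        assert sorted(supercover_cells(r0, c0, r1, c1)) == expect

    def test_exact_diagonal_includes_corner_touched_cells(self):
        # the segment (0,0)-(2,2) passes exactly through cell corners
        cells = set(supercover_cells(0, 0, 2, 2))
        assert {(0, 1), (1, 0), (1, 2), (2, 1)} <= cells


class TestBuildTransects:
    def test_horizontal_pair(self):
        feats = [
            TerrainFeature("peak", 1, 0, 900.0),
            TerrainFeature("foothill", 1, 5, 10.0),
        ]
        (tr,) = build_transects(feats)
        assert tr.cells == [(1, c) for c in range(6)]

    def test_equidistant_tie_breaks_to_lower_row_major(self):
        feats = [
            TerrainFeature("peak", 2, 2, 900.0),
            TerrainFeature("foothill", 0, 2, 10.0),
            TerrainFeature("foothill", 4, 2, 10.0),
        ]
        transects = build_transects(feats)
        endpoints = {(t.cells[0], t.cells[-1]) for t in transects}
        # peak pairs with the (0,2) foothill (lower row-major); both
        # foothills pair back to the peak -> 2 deduplicated transects
        assert len(transects) == 2
        assert ((2, 2), (0, 2)) in endpoints or ((0, 2), (2, 2)) in endpoints

    def test_missing_feature_kind_gives_no_transects(self):
        assert build_transects([TerrainFeature("peak", 0, 0, 1.0)]) == []


class TestFitTransect:
    def test_perfect_line(self):
        z = np.linspace(0, 1800, 10)
        t = 20.0 - 0.0065 * z
        beta, r2, p, n = fit_transect(z, t)
        assert beta == pytest.approx(-0.0065)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-6 and n == 10

    def test_flat_response(self):
        beta, r2, _, _ = fit_transect([0, 100, 200, 300], [5.0, 5.0, 5.0, 5.0])
        assert beta == 0.0 and r2 == 0.0

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(5)
        z = rng.uniform(0, 2000, 20)
        t = 18 - 0.006 * z + rng.normal(0, 0.3, 20)
        beta, r2, p, n = fit_transect(z, t)
        # closed-form OLS oracle
        zc, tc = z - z.mean(), t - t.mean()
        slope = (zc * tc).sum() / (zc**2).sum()
        resid = tc - slope * zc
        r2_hand = 1 - (resid**2).sum() / (tc**2).sum()
        se = np.sqrt((resid**2).sum() / (n - 2) / (zc**2).sum())
        from scipy import stats as ss

        p_hand = 2 * ss.t.sf(abs(slope / se), n - 2)
        assert beta == pytest.approx(slope)
        assert r2 == pytest.approx(r2_hand)
        assert p == pytest.approx(p_hand, rel=1e-6)

    def test_too_few_or_degenerate_is_invalid(self):
        assert fit_transect([0, 100], [1, 2]) is None
        assert fit_transect([5, 5, 5], [1, 2, 3]) is None


class TestAggregateBetas:
    def test_median_above_threshold(self):
        betas = [-0.006] * 11 + [-0.02]  # 12 transects, skewed by one
        assert aggregate_betas(betas, 10) == pytest.approx(np.median(betas))
        assert aggregate_betas(betas, 10) != pytest.approx(np.mean(betas))

    def test_mean_at_or_below_threshold(self):
        betas = [-0.005, -0.007, -0.02]
        assert aggregate_betas(betas, 10) == pytest.approx(np.mean(betas))

    def test_always_median_switch(self):
        betas = [-0.005, -0.007, -0.02]
        assert aggregate_betas(betas, 10, always_median=True) == pytest.approx(
            np.median(betas)
        )


class TestSlrtMap:
    def test_noise_free_recovery_is_exact(self):
        scen = SyntheticScenario(seed=3, lapse_noise_sd=0.0)
        dem = make_dem(scen)
        temp = make_temperature_field(dem, scen)
        coarse = aggregate(dem, scen.coarse_factor)
        lapse, count = slrt_map(temp, dem, coarse)
        mapped = np.isfinite(lapse.values)
        assert mapped.any()
        np.testing.assert_allclose(lapse.values[mapped], scen.true_lapse, rtol=1e-9)
        assert np.all(count.values[~mapped] == 0)

    def test_noisy_recovery_within_tolerance(self, dem, temperature, scenario):
        coarse = aggregate(dem, scenario.coarse_factor)
        lapse, count = slrt_map(temperature, dem, coarse)
        mapped = np.isfinite(lapse.values)
        assert mapped.sum() >= 5
        assert np.nanmax(np.abs(lapse.values - scenario.true_lapse)) <= 0.3

    def test_inversion_gives_negative_slrt(self):
        scen = SyntheticScenario(seed=3, lapse_noise_sd=0.0, true_lapse=5.0)
        dem = make_dem(scen)
        temp = make_temperature_field(dem, scen)
        inverted = temp.like(2 * temp.values.mean() - temp.values)
        coarse = aggregate(dem, scen.coarse_factor)
        lapse, _ = slrt_map(inverted, dem, coarse)
        vals = lapse.values[np.isfinite(lapse.values)]
        assert vals.size and np.all(vals < 0)

    def test_retained_transects_meet_filters(self, dem, temperature, scenario):
        coarse = aggregate(dem, scenario.coarse_factor)
        _, _, table = slrt_map(temperature, dem, coarse, return_table=True)
        assert len(table) > 0
        assert (table["r_squared"] >= 0.5).all()
        assert (table["p_value"] <= 0.05).all()
        assert (table["n"] >= 3).all()

    def test_geometry_mismatch_raises(self, dem, scenario):
        other = dem.like(dem.values)
        other.lat_origin += 1.0
        with pytest.raises(ValueError, match="geometry"):
            slrt_map(other, dem, aggregate(dem, 10))
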