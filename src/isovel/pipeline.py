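"""Stage-by-stage pipeline over a working directory of artifacts.

Each stage reads the artifacts of its upstream stages from ``outdir`` and
writes its own; ``run_all`` chains every stage on the synthetic scenario.
All file formats are the package's standard ones (GeoTIFF/NetCDF rasters,
CSV tables, JSON parameter dumps), so any stage can also be fed real data
prepared in the same layout.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import elevlat as _elevlat
from . import slrt as _slrt
from . import stations as _stations
from . import threat as _threat
from . import thermo as _thermo
from . import tracking as _tracking
from . import velocity as _velocity
from .config import RunConfig
from .grids import DecadalClimatology, aggregate, read_grid, write_grid
from . import synthetic as _synthetic

logger = logging.getLogger("isovel")

STAGES = (
    "simulate",
    "malrt",
    "slrt",
    "velocity",
    "threat",
    "elevlat",
    "stations",
    "track",
    "all",
)


def _p(outdir, name: str) -> str:
    return os.path.join(outdir, name)


def _load_velocity(outdir, method: str) -> _velocity.VelocityMap:
    return _velocity.VelocityMap(
        velocity=read_grid(_p(outdir, f"velocity_{method}.tif")),
        method=method,
        warming_rate=read_grid(_p(outdir, "warming_rate.tif")),
        lapse_used=read_grid(_p(outdir, f"lapse_{method}.tif")),
    )


def run_stage(stage: str, config: RunConfig, outdir) -> None:
    """Run one named stage (or ``all``) into ``outdir``."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage: {stage}; expected one of {STAGES}")
    os.makedirs(outdir, exist_ok=True)
    if stage == "all":
        for s in STAGES[:-1]:
            run_stage(s, config, outdir)
        return
    logger.info("stage %s: seed=%d outdir=%s", stage, config.seed, outdir)
    globals()[f"_stage_{stage}"](config, outdir)


def _stage_simulate(cfg: RunConfig, outdir) -> None:
    scen = cfg.scenario
    dem = _synthetic.make_dem(scen)
    write_grid(dem, _p(outdir, "dem_fine.tif"))
    coarse = aggregate(dem, scen.coarse_factor)
    write_grid(coarse, _p(outdir, "dem_coarse.tif"))
    write_grid(
        _synthetic.make_island_mask(scen, coarse), _p(outdir, "island_mask.tif")
    )
    early, late = _synthetic.make_decadal_pair(dem, scen)
    write_grid(early.temperature, _p(outdir, "clim_early_temp.nc"))
    write_grid(early.vapour_pressure, _p(outdir, "clim_early_vap.nc"))
    write_grid(late.temperature, _p(outdir, "clim_late_temp.nc"))
    write_grid(late.vapour_pressure, _p(outdir, "clim_late_vap.nc"))
    _stations.write_station_csv(
        _synthetic.make_stations(dem, scen), _p(outdir, "stations.csv")
    )
    logger.info(
        "simulate: %dx%d fine grid, %d stations",
        scen.n_rows_fine, scen.n_cols_fine, scen.station_count,
    )


def _read_climatologies(cfg: RunConfig, outdir):
    early = DecadalClimatology(
        temperature=read_grid(_p(outdir, "clim_early_temp.nc")),
        vapour_pressure=read_grid(_p(outdir, "clim_early_vap.nc")),
        period_label="early decade",
    )
    late = DecadalClimatology(
        temperature=read_grid(_p(outdir, "clim_late_temp.nc")),
        vapour_pressure=read_grid(_p(outdir, "clim_late_vap.nc")),
        period_label="late decade",
    )
    return early, late


def _stage_malrt(cfg: RunConfig, outdir) -> None:
    factor = cfg.scenario.coarse_factor
    _, late = _read_climatologies(cfg, outdir)
    coarse_dem = read_grid(_p(outdir, "dem_coarse.tif"))
    clim = DecadalClimatology(
        temperature=aggregate(late.temperature, factor),
        vapour_pressure=aggregate(late.vapour_pressure, factor),
        period_label=late.period_label,
    )
    lapse = _thermo.malrt_grid(clim, coarse_dem)
    write_grid(lapse, _p(outdir, "lapse_malrt.tif"))
    logger.info("malrt: %d finite cells", int(np.isfinite(lapse.values).sum()))


def _stage_slrt(cfg: RunConfig, outdir) -> None:
    dem = read_grid(_p(outdir, "dem_fine.tif"))
    _, late = _read_climatologies(cfg, outdir)
    coarse = read_grid(_p(outdir, "dem_coarse.tif"))
    lapse, count, table = _slrt.slrt_map(
        late.temperature,
        dem,
        coarse,
        r2_min=cfg.r2_min,
        p_max=cfg.p_max,
        median_threshold=cfg.median_threshold,
        prominence_min=cfg.prominence_min,
        return_table=True,
    )
    write_grid(lapse, _p(outdir, "lapse_slrt.tif"))
    write_grid(count, _p(outdir, "transect_count.tif"))
    table.to_csv(_p(outdir, "transects.csv"), index=False)
    logger.info(
        "slrt: %d retained transect fits, %d mapped cells",
        len(table), int(np.isfinite(lapse.values).sum()),
    )


def _stage_velocity(cfg: RunConfig, outdir) -> None:
    factor = cfg.scenario.coarse_factor
    early, late = _read_climatologies(cfg, outdir)
    rate = _velocity.warming_rate(
        DecadalClimatology(aggregate(early.temperature, factor),
                           aggregate(early.vapour_pressure, factor)),
        DecadalClimatology(aggregate(late.temperature, factor),
                           aggregate(late.vapour_pressure, factor)),
        years=cfg.years,
    )
    write_grid(rate, _p(outdir, "warming_rate.tif"))

    vc = _velocity.constant_lrt_velocity(rate, cfg.constant_lrt)
    write_grid(vc.lapse_used, _p(outdir, "lapse_constant.tif"))
    write_grid(vc.velocity, _p(outdir, "velocity_constant.tif"))
    for method in ("malrt", "slrt"):
        lapse = read_grid(_p(outdir, f"lapse_{method}.tif"))
        vm = _velocity.vertical_velocity(rate, lapse, method)
        write_grid(vm.velocity, _p(outdir, f"velocity_{method}.tif"))
    logger.info("velocity: three maps written (constant %.2f °C/km control)",
                cfg.constant_lrt)


def _stage_threat(cfg: RunConfig, outdir) -> None:
    v_malrt = _load_velocity(outdir, "malrt")
    v_slrt = _threat.remove_near_zero_lapse(
        _load_velocity(outdir, "slrt"), cfg.outlier_fraction
    )
    tm = _threat.consensus_threat(v_malrt, v_slrt, q=cfg.q, mode=cfg.threat_mode)
    write_grid(tm.flags, _p(outdir, "threat.tif"))
    tm.summary().to_csv(_p(outdir, "threat_summary.csv"), index=False)
    logger.info("threat: flagged fraction %.3f", tm.flagged_fraction())


def _stage_elevlat(cfg: RunConfig, outdir) -> None:
    v_malrt = _load_velocity(outdir, "malrt")
    coarse_dem = read_grid(_p(outdir, "dem_coarse.tif"))
    island = read_grid(_p(outdir, "island_mask.tif"))
    plane = _elevlat.bin_elevation_latitude(
        v_malrt, coarse_dem, cfg.elev_bin_width, cfg.lat_bin_width
    )
    plane.to_csv(_p(outdir, "elevlat.csv"), index=False)
    cells = _elevlat.cell_table(v_malrt, coarse_dem, island)
    _elevlat.fit_velocity_regression(cells).to_csv(
        _p(outdir, "velocity_regression.csv"), index=False
    )
    labels = np.where(
        cells["island"],
        cells["hemisphere"] + ". island",
        cells["hemisphere"] + ". mainland",
    )
    try:
        anova, tukey = _elevlat.compare_groups(cells["velocity"], labels)
        anova.to_csv(_p(outdir, "group_anova.csv"), index=False)
        tukey.to_csv(_p(outdir, "group_tukey.csv"), index=False)
    except ValueError as exc:
        logger.warning("elevlat: group comparison skipped (%s)", exc)
    logger.info("elevlat: %d plane cells from %d map cells",
                len(plane), len(cells))


def _stage_stations(cfg: RunConfig, outdir) -> None:
    records = _stations.read_station_csv(_p(outdir, "stations.csv"))
    retained = _stations.filter_stations(records)
    coarse = read_grid(_p(outdir, "dem_coarse.tif"))
    sites = _stations.build_sites(retained, coarse)
    pd.DataFrame(
        [
            {"center_row": s.center[0], "center_col": s.center[1],
             "n_stations": s.n_stations, "lrt_c_per_km": s.lrt}
            for s in sites
        ]
    ).to_csv(_p(outdir, "site_lrts.csv"), index=False)
    usable = [s for s in sites if s.lrt is not None]
    if len(usable) >= 3:
        validation = _stations.validate_lapse_maps(
            usable,
            read_grid(_p(outdir, "lapse_malrt.tif")),
            read_grid(_p(outdir, "lapse_slrt.tif")),
        )
        validation.to_csv(_p(outdir, "validation.csv"), index=False)
    else:
        logger.warning("stations: only %d usable sites; validation skipped",
                       len(usable))
    logger.info("stations: %d/%d retained, %d sites",
                len(retained), len(records), len(sites))


def _stage_track(cfg: RunConfig, outdir) -> None:
    v_malrt = _load_velocity(outdir, "malrt")
    shifts_path = _p(outdir, "range_shifts.csv")
    if not os.path.exists(shifts_path):
        records = _synthetic.make_range_shifts(v_malrt, cfg.scenario)
        _tracking.write_range_shift_csv(records, shifts_path)
    records = _tracking.read_range_shift_csv(shifts_path)
    kept = _tracking.filter_study_extent(records)
    results = _tracking.tracking_by_group(
        kept,
        v_malrt,
        n_resample=cfg.n_resample,
        iterations=cfg.iterations,
        alpha=cfg.alpha,
        seed=cfg.seed,
    )
    pd.DataFrame(
        [
            {"taxon_group": r.taxon_group, "region_id": r.region_id,
             "probability": r.probability, "n_records_used": r.n_records_used,
             "n_resample": r.n_resample, "n_iterations": r.n_iterations,
             "alpha": r.alpha, "seed": r.seed,
             "mean_abs_velocity": r.mean_abs_velocity}
            for r in results
        ]
    ).to_csv(_p(outdir, "tracking_results.csv"), index=False)
    try:
        a, b, _ = _tracking.fit_probit_curve(results)
        with open(_p(outdir, "tracking_curve.json"), "w") as fh:
            json.dump({"intercept": a, "slope": b}, fh, indent=2, sort_keys=True)
    except Exception as exc:  # probit may not converge on tiny runs
        logger.warning("track: probit curve not fitted (%s)", exc)
    logger.info("track: %d/%d records within extent, %d taxon-region groups",
                len(kept), len(records), len(results))
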