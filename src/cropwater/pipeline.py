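"""End-to-end pipeline: configuration, stage ordering, manifest, reports.

Stages run in dependency order: station ET0 → Thiessen regionalization →
crop coefficients → demand (Pe, ETc, CWR, IWR) → aggregation → water
balance → trends → variable importance. Every stage's output is a plain
CSV under the configured output directory, and a ``manifest.json`` records
the configuration hash, seed and row counts so an identical run can be
reproduced from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import balance_trends, crop_kc, demand, importance, io, meteo_et0, spatial_regions
from .errors import DataError, InputError
from .synthetic_data import SyntheticScenario, gen_actuals, generate_all

log = logging.getLogger(__name__)

#: Months defining the growing season for the regional temperature feature.
GROWING_SEASON_MONTHS = tuple(range(4, 11))


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of one pipeline run; unknown keys in a YAML file are rejected.

    Input paths are optional: any left as None is synthesized from the
    seeded scenario, so a config with no paths runs fully synthetic.
    """

    seed: int = 0
    out_dir: str = "outputs"
    # physical constants (documented defaults: δ empirical effective-rain
    # coefficient; Angstrom a_s/b_s and albedo are the FAO reference values)
    delta_coef: float = demand.DELTA_COEF
    clamp_cwr: bool = True
    angstrom_as: float = meteo_et0.ANGSTROM_AS
    angstrom_bs: float = meteo_et0.ANGSTROM_BS
    albedo: float = meteo_et0.ALBEDO
    balanced_band_m3: float = balance_trends.BALANCED_BAND_M3
    scarcity_threshold_m3: float = balance_trends.SERIOUS_SCARCITY_M3
    thiessen_metric: str = "euclidean"
    actuals_bias: float | None = -0.34
    actuals_noise_sd_m3: float = 0.0
    # optional input files; None → synthesize
    stations_file: str | None = None
    meteo_file: str | None = None
    regions_file: str | None = None
    areas_file: str | None = None
    efficiency_file: str | None = None
    actuals_file: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config: PipelineConfig) -> dict:
    """Read configured input files, synthesizing whatever is missing."""
    paths = (
        config.stations_file,
        config.meteo_file,
        config.regions_file,
        config.areas_file,
        config.efficiency_file,
    )
    scenario = SyntheticScenario.xinjiang_like(seed=config.seed)
    if all(p is None for p in paths):
        inputs = generate_all(scenario)
    elif any(p is None for p in paths):
        raise InputError(
            "provide stations, meteo, regions, areas and efficiency files together, or none"
        )
    else:
        regions, basins = io.read_regions(config.regions_file)
        inputs = {
            "stations": io.read_stations(config.stations_file),
            "meteo": io.read_station_monthly(config.meteo_file),
            "regions": regions,
            "areas": io.read_crop_areas(config.areas_file),
            "efficiency": io.read_efficiency(config.efficiency_file),
            "basins": basins,
        }
    inputs["scenario"] = scenario
    return inputs


def regionalize_climate(
    stations: pd.DataFrame,
    meteo: pd.DataFrame,
    et0_table: pd.DataFrame,
    regions,
    metric: str = "euclidean",
) -> pd.DataFrame:
    """Thiessen-assign every region's cells and build its monthly series.

    Carries ET0, temperature extremes and means, precipitation, 2 m wind
    and relative humidity onto (region_id, basin_id, year, month) rows.
    """
    height = meteo["anemometer_height"].fillna(meteo_et0.DEFAULT_ANEMOMETER_HEIGHT).to_numpy(float)
    series = meteo[["station_id", "year", "month", "t_max", "t_min", "t_mean", "precip", "rel_humidity"]].copy()
    series["u2"] = meteo_et0.wind_at_2m(meteo["wind_speed"].to_numpy(float), height)
    series = series.merge(et0_table, on=["station_id", "year", "month"], validate="one_to_one")

    frames = []
    for region in regions:
        assigned = spatial_regions.thiessen_assign(stations, region.xy, metric=metric)
        frames.append(spatial_regions.region_climate(list(assigned), series, region))
    return pd.concat(frames, ignore_index=True)


def build_kc_table(region_climate: pd.DataFrame, crops=crop_kc.CROPS) -> pd.DataFrame:
    """Monthly Kc per region-crop-year with per-year climate adjustment.

    Stage-mean 2 m wind and RHmin (from monthly temperature extremes) over
    the mid and late stage months of each region-year feed the Kc_mid and
    Kc_end adjustments; the four-stage daily curve is then averaged to
    calendar months.
    """
    rows = []
    rhmin = crop_kc.rh_min_from_temps(
        region_climate["t_min"].to_numpy(float), region_climate["t_max"].to_numpy(float)
    )
    clim = region_climate.assign(rh_min=rhmin)
    for crop in crops:
        calendar_ = crop_kc.default_calendar(crop)
        profile = crop_kc.default_profile(crop)
        months = crop_kc.stage_months(calendar_)
        for (region_id, year), sub in clim.groupby(["region_id", "year"]):
            mid = sub[sub["month"].isin(months["mid"])]
            late = sub[sub["month"].isin(months["late"])]
            climate = crop_kc.KcAdjustClimate(
                u2_mid=float(mid["u2"].mean()),
                rh_min_mid=float(mid["rh_min"].mean()),
                u2_end=float(late["u2"].mean()),
                rh_min_end=float(late["rh_min"].mean()),
            )
            adj = crop_kc.adjusted_profile(profile, climate)
            curve = crop_kc.build_kc_curve(calendar_, adj)
            monthly = crop_kc.monthly_kc(curve, int(year))
            for month, kc in monthly.items():
                rows.append(
                    {"region_id": region_id, "crop": crop, "year": int(year), "month": int(month), "kc": kc}
                )
    return pd.DataFrame(rows)


def growing_season_temps(region_climate: pd.DataFrame) -> pd.DataFrame:
    """Growing-season (Apr–Oct) mean temperature per region-year."""
    sub = region_climate[region_climate["month"].isin(GROWING_SEASON_MONTHS)]
    out = sub.groupby(["region_id", "year"], as_index=False)["t_mean"].mean()
    return out.rename(columns={"t_mean": "temperature"})


def basin_annual_climate(region_climate: pd.DataFrame) -> pd.DataFrame:
    """Basin-year annual mean temperature and annual total precipitation.

    Regions are averaged unweighted within a basin; precipitation is summed
    over months within each region first.
    """
    per_region = region_climate.groupby(["basin_id", "region_id", "year"]).agg(
        t_mean=("t_mean", "mean"), precip=("precip", "sum")
    )
    return per_region.groupby(["basin_id", "year"]).mean().reset_index()


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Execute every stage; return all tables and write them plus a manifest."""
    inputs = _load_inputs(config)
    stations, meteo = inputs["stations"], inputs["meteo"]
    regions, areas = inputs["regions"], inputs["areas"]
    basins = inputs["basins"]

    meteo_et0.validate_station_table(meteo)
    et0_table = meteo_et0.station_et0_series(
        meteo, angstrom_as=config.angstrom_as, angstrom_bs=config.angstrom_bs, albedo=config.albedo
    )
    region_climate = regionalize_climate(
        stations, meteo, et0_table, regions, metric=config.thiessen_metric
    )
    kc_table = build_kc_table(region_climate)
    demand_table = demand.build_demand_table(
        region_climate,
        kc_table,
        areas,
        inputs["efficiency"],
        basins,
        delta_coef=config.delta_coef,
        clamp=config.clamp_cwr,
    )

    if config.actuals_file is not None:
        actuals = io.read_actuals(config.actuals_file)
    else:
        actuals = gen_actuals(
            inputs["scenario"], demand_table,
            bias=config.actuals_bias, noise_sd_m3=config.actuals_noise_sd_m3,
        )
    region_year_iwr = demand.aggregate_iwr(demand_table, by=("region", "year"))
    balance = balance_trends.build_balance_table(
        region_year_iwr,
        actuals,
        basins,
        balanced_band=config.balanced_band_m3,
        serious_threshold=config.scarcity_threshold_m3,
    )

    basin_climate = basin_annual_climate(region_climate)
    annual_iwr_basin = demand.aggregate_iwr(demand_table, by=("basin", "year"))
    trend_frames = [
        balance_trends.trend_table(
            basin_climate.rename(columns={"t_mean": "value"}), ["basin_id"], "value"
        ).assign(variable="temperature_c"),
        balance_trends.trend_table(
            basin_climate.rename(columns={"precip": "value"}), ["basin_id"], "value"
        ).assign(variable="precip_mm"),
        balance_trends.trend_table(
            annual_iwr_basin.rename(columns={"iwr_billion_m3": "value"}), ["basin_id"], "value"
        ).assign(variable="iwr_billion_m3"),
    ]
    trends = pd.concat(trend_frames, ignore_index=True)

    features = importance.build_feature_table(demand_table, areas, growing_season_temps(region_climate))
    importance_table = importance.importance_report(features, seed=config.seed)

    results = {
        "stations": stations,
        "meteo": meteo,
        "areas": areas,
        "efficiency": inputs["efficiency"],
        "et0": et0_table,
        "region_climate": region_climate,
        "kc": kc_table,
        "demand": demand_table,
        "actuals": actuals,
        "balance": balance,
        "basin_balance": balance_trends.basin_balance(balance, config.balanced_band_m3),
        "trends": trends,
        "features": features,
        "importance": importance_table,
    }
    results["report"] = report(results)
    if write:
        write_outputs(results, config)
    return results


def report(results: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Summary tables at the reporting granularity of the study.

    Volumes are expressed in 10⁹ m³ at two decimals: annual IWR per basin,
    monthly IWR climatology per basin, annual IWR and shares per crop,
    labelled per-region balance, and the trend table. Sections whose inputs
    are missing are skipped with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    if "demand" in results:
        d = results["demand"]
        annual_basin = demand.aggregate_iwr(d, by=("basin", "year"))
        out["annual_iwr_by_basin"] = (
            annual_basin.pivot(index="year", columns="basin_id", values="iwr_billion_m3").round(2).reset_index()
        )
        monthly = demand.aggregate_iwr(d, by=("basin", "year", "month"))
        clim = monthly.groupby(["basin_id", "month"], as_index=False)["iwr_billion_m3"].mean()
        out["monthly_iwr_climatology_by_basin"] = (
            clim.pivot(index="month", columns="basin_id", values="iwr_billion_m3").round(2).reset_index()
        )
        crop_year = demand.aggregate_iwr(d, by=("crop", "year"))
        totals = crop_year.groupby("year")["iwr_m3"].transform("sum")
        crop_year["share_pct"] = (crop_year["iwr_m3"] / totals * 100.0).round(2)
        crop_year["iwr_billion_m3"] = crop_year["iwr_billion_m3"].round(2)
        out["annual_iwr_by_crop"] = crop_year[["crop", "year", "iwr_billion_m3", "share_pct"]]
    else:
        log.warning("report: demand table missing; IWR sections skipped")
    if "balance" in results:
        bal = results["balance"].copy()
        for col in ("ia_m3", "iwr_m3", "delta_w_m3"):
            bal[col.replace("_m3", "_billion_m3")] = (bal[col] / 1e9).round(2)
        out["region_balance"] = bal[
            ["region_id", "basin_id", "year", "ia_billion_m3", "iwr_billion_m3", "delta_w_billion_m3", "label", "serious_scarcity"]
        ]
    else:
        log.warning("report: balance table missing; balance section skipped")
    if "trends" in results:
        out["trend_report"] = results["trends"].round(4)
    else:
        log.warning("report: trends table missing; trend section skipped")
    return out


def write_outputs(results: Mapping, config: PipelineConfig) -> Path:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    for name, table in results.items():
        if name == "report":
            for rname, rtable in table.items():
                io.write_table(rtable, out_dir / f"report_{rname}.csv")
                counts[f"report_{rname}"] = len(rtable)
        elif isinstance(table, pd.DataFrame):
            io.write_table(table, out_dir / f"{name}.csv")
            counts[name] = len(table)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "row_counts": counts,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out_dir
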