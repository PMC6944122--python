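"""Effective precipitation, crop and irrigation water requirements.

Per region-crop-month:

    Pe  = δ · P                      (effective precipitation, δ = 0.52)
    ETc = Kc · ET0                   (crop evapotranspiration)
    CWR = max(ETc − Pe, 0)           (crop water requirement; clamp optional)
    IWR = A · CWR / Ie               (gross withdrawal; A in km², CWR in mm,
                                      1 mm over 1 km² = 1000 m³)

Irrigation efficiency Ie is a per-region scalar in (0, 1]. Volumes are kept
in m³ internally and reported in 10⁹ m³ ("billion m³") at two decimals.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataError, InputError

#: Empirical effective-utilization coefficient of precipitation.
DELTA_COEF = 0.52

#: Cubic metres delivered by 1 mm of water depth over 1 km².
M3_PER_MM_KM2 = 1000.0

#: Published prefecture-level irrigation efficiencies for Xinjiang
#: (provincial mean 0.68).
XINJIANG_IE: Mapping[str, float] = {
    "Aksu": 0.70,
    "Aletai": 0.62,
    "Bazhou": 0.65,
    "Bozhou": 0.60,
    "Changji": 0.70,
    "Hami": 0.66,
    "Hotan": 0.72,
    "Kashgar": 0.63,
    "Kezhou": 0.60,
    "Karamay": 0.79,
    "Shihezi": 0.71,
    "Tacheng": 0.69,
    "Turpan": 0.79,
    "Urumqi": 0.78,
    "Yili": 0.73,
}

XINJIANG_IE_MEAN = 0.68

DEMAND_COLUMNS = (
    "region_id",
    "basin_id",
    "crop",
    "year",
    "month",
    "kc",
    "et0_month",
    "precip",
    "pe",
    "etc",
    "cwr",
    "area_km2",
    "ie",
    "iwr_m3",
)


def effective_precip(p, delta_coef: float = DELTA_COEF):
    """Effective precipitation Pe = δ·P (mm)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise InputError("precipitation must be non-negative")
    if not 0.0 <= delta_coef <= 1.0:
        raise InputError("delta_coef must lie in [0, 1]")
    out = p_arr * delta_coef
    return float(out) if np.ndim(p) == 0 else out


def crop_et(kc, et0):
    """Crop evapotranspiration ETc = Kc·ET0 (mm)."""
    kc_arr = np.asarray(kc, dtype=float)
    et0_arr = np.asarray(et0, dtype=float)
    if np.any(kc_arr < 0) or np.any(et0_arr < 0):
        raise InputError("kc and et0 must be non-negative")
    out = kc_arr * et0_arr
    return float(out) if np.ndim(kc) == 0 and np.ndim(et0) == 0 else out


def crop_water_requirement(etc, pe, clamp: bool = True):
    """Crop water requirement CWR = ETc − Pe (mm).

    Negative monthly values (wet months) are clamped at zero by default;
    ``clamp=False`` returns the raw difference.
    """
    etc_arr = np.asarray(etc, dtype=float)
    pe_arr = np.asarray(pe, dtype=float)
    if np.any(etc_arr < 0) or np.any(pe_arr < 0):
        raise InputError("etc and pe must be non-negative")
    out = etc_arr - pe_arr
    if clamp:
        out = np.maximum(out, 0.0)
    return float(out) if np.ndim(etc) == 0 and np.ndim(pe) == 0 else out


def irrigation_water_requirement(area_km2, cwr, ie):
    """Gross irrigation water requirement IWR = A·CWR/Ie in m³."""
    area = np.asarray(area_km2, dtype=float)
    cwr_arr = np.asarray(cwr, dtype=float)
    ie_arr = np.asarray(ie, dtype=float)
    if np.any(area < 0) or np.any(cwr_arr < 0):
        raise InputError("area and cwr must be non-negative")
    if np.any(ie_arr <= 0) or np.any(ie_arr > 1):
        raise InputError("irrigation efficiency must lie in (0, 1]")
    out = area * cwr_arr * M3_PER_MM_KM2 / ie_arr
    scalar = np.ndim(area_km2) == 0 and np.ndim(cwr) == 0 and np.ndim(ie) == 0
    return float(out) if scalar else out


def _efficiency_mapping(efficiency) -> Mapping[str, float]:
    if isinstance(efficiency, pd.DataFrame):
        if not {"region_id", "ie"} <= set(efficiency.columns):
            raise DataError("efficiency table needs columns region_id, ie")
        efficiency = dict(zip(efficiency["region_id"], efficiency["ie"]))
    bad = {r: v for r, v in efficiency.items() if not 0 < v <= 1}
    if bad:
        raise DataError(f"irrigation efficiencies outside (0, 1]: {bad}")
    return efficiency


def build_demand_table(
    region_climate: pd.DataFrame,
    kc_table: pd.DataFrame,
    areas: pd.DataFrame,
    efficiency,
    basins: Mapping[str, str],
    delta_coef: float = DELTA_COEF,
    clamp: bool = True,
) -> pd.DataFrame:
    """Assemble the per region-crop-month demand table.

    ``region_climate`` needs (region_id, year, month, et0_month, precip);
    ``kc_table`` needs (region_id, crop, year, month, kc); ``areas`` needs
    (region_id, year, crop, area_km2) with the annual area applied to every
    month of that year. Regions with planted area but no efficiency entry or
    no basin mapping fail loudly.
    """
    for frame, cols, name in (
        (region_climate, {"region_id", "year", "month", "et0_month", "precip"}, "region climate"),
        (kc_table, {"region_id", "crop", "year", "month", "kc"}, "kc table"),
        (areas, {"region_id", "year", "crop", "area_km2"}, "areas table"),
    ):
        missing = cols - set(frame.columns)
        if missing:
            raise DataError(f"{name} missing column(s): {', '.join(sorted(missing))}")
    if (areas["area_km2"] < 0).any():
        raise DataError("negative crop area")

    eff = _efficiency_mapping(efficiency)
    regions_used = sorted(set(areas["region_id"]))
    no_eff = [r for r in regions_used if r not in eff]
    if no_eff:
        raise DataError(f"region(s) with crop area but no efficiency entry: {', '.join(no_eff)}")
    no_basin = [r for r in regions_used if r not in basins]
    if no_basin:
        raise DataError(f"region(s) mapped to no basin: {', '.join(no_basin)}")

    df = kc_table.merge(region_climate, on=["region_id", "year", "month"], how="left", validate="many_to_one")
    if df["et0_month"].isna().any():
        miss = df.loc[df["et0_month"].isna(), ["region_id", "year", "month"]].head(5).to_dict("records")
        raise DataError(f"region climate missing for kc rows: {miss}")
    df = df.merge(areas, on=["region_id", "year", "crop"], how="inner", validate="many_to_one")

    df["pe"] = effective_precip(df["precip"].to_numpy(float), delta_coef)
    df["etc"] = crop_et(df["kc"].to_numpy(float), df["et0_month"].to_numpy(float))
    df["cwr"] = crop_water_requirement(df["etc"].to_numpy(float), df["pe"].to_numpy(float), clamp=clamp)
    df["ie"] = df["region_id"].map(eff)
    df["basin_id"] = df["region_id"].map(basins)
    cwr_vol = np.maximum(df["cwr"].to_numpy(float), 0.0) if not clamp else df["cwr"].to_numpy(float)
    # unclamped mode still reports a non-negative withdrawal volume
    df["iwr_m3"] = irrigation_water_requirement(
        df["area_km2"].to_numpy(float), cwr_vol, df["ie"].to_numpy(float)
    )
    return df[list(DEMAND_COLUMNS)].sort_values(["region_id", "crop", "year", "month"]).reset_index(drop=True)


_GROUP_KEYS = {"year": "year", "month": "month", "region": "region_id", "basin": "basin_id", "crop": "crop"}


def aggregate_iwr(records: pd.DataFrame, by: Iterable[str]) -> pd.DataFrame:
    """Sum IWR over the complement of the grouping keys.

    ``by`` is a subset of {year, month, region, basin, crop}. Adds a
    ``iwr_billion_m3`` convenience column (10⁹ m³)."""
    keys = [(_GROUP_KEYS[k] if k in _GROUP_KEYS else k) for k in by]
    unknown = [k for k in keys if k not in records.columns]
    if unknown:
        raise InputError(f"unknown grouping key(s): {', '.join(unknown)}")
    if "basin_id" in keys and records["basin_id"].isna().any():
        bad = sorted(set(records.loc[records["basin_id"].isna(), "region_id"]))
        raise DataError(f"region(s) mapped to no basin: {', '.join(bad)}")
    # aggregate through canonical per-region subtotals so that basin (or
    # province) totals are bit-identical to the sum of their regions' totals
    if "region_id" in records.columns and "region_id" not in keys:
        sub = records.groupby(keys + ["region_id"], as_index=False, sort=True)["iwr_m3"].sum()
    else:
        sub = records
    out = sub.groupby(keys, as_index=False, sort=True)["iwr_m3"].sum()
    out["iwr_billion_m3"] = out["iwr_m3"] / 1e9
    return out


def crop_share(records: pd.DataFrame, crop: str, year: int) -> float:
    """Share (%) of ``year``'s total IWR attributable to ``crop``."""
    year_rows = records[records["year"] == year]
    total = year_rows["iwr_m3"].sum()
    if total <= 0:
        raise DataError(f"total IWR for year {year} is zero; shares undefined")
    return float(year_rows.loc[year_rows["crop"] == crop, "iwr_m3"].sum() / total * 100.0)
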