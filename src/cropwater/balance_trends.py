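"""Regional water balance and linear trend estimation.

The soil water balance Pe + I + Qg − ETc − R − D = ΔW reduces, when surface
runoff R, deep drainage D and the water-table contribution Qg are negligible
(flat irrigated land, deep water table, low-intensity rain), to

    ΔW = Ia − IWR

at region-year granularity: positive ΔW is surplus (actual withdrawal
exceeds requirement), negative is scarcity. The neglected terms are kept as
explicit zero-valued fields so the full balance can be exercised and
extended. Trends are ordinary least squares on calendar year, reported per
year and per decade.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InputError

#: |ΔW| below this (m³) counts as balanced rather than surplus/scarcity.
BALANCED_BAND_M3 = 0.01e9

#: ΔW at or below this (m³) is flagged as serious scarcity in reports.
SERIOUS_SCARCITY_M3 = -1.0e9


@dataclass(frozen=True)
class WaterBalanceRecord:
    """One region-year balance; qg, r, d are retained but zero by default."""

    region_id: str
    year: int
    ia: float
    iwr: float
    delta_w: float
    qg: float = 0.0
    r: float = 0.0
    d: float = 0.0


@dataclass(frozen=True)
class TrendResult:
    """OLS trend of an annual series; slope_per_decade = 10 × slope_per_year."""

    slope_per_year: float
    slope_per_decade: float
    intercept: float
    n_points: int


def water_balance(ia, iwr):
    """ΔW = Ia − IWR (m³); sign conveys surplus (+) vs scarcity (−)."""
    ia_arr = np.asarray(ia, dtype=float)
    iwr_arr = np.asarray(iwr, dtype=float)
    if np.any(ia_arr < 0) or np.any(iwr_arr < 0):
        raise InputError("ia and iwr must be non-negative")
    out = ia_arr - iwr_arr
    return float(out) if np.ndim(ia) == 0 and np.ndim(iwr) == 0 else out


def classify_balance(delta_w, balanced_band: float = BALANCED_BAND_M3):
    """Label ΔW as ``surplus`` / ``balanced`` / ``scarcity``."""
    arr = np.asarray(delta_w, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError("delta_w must be finite")
    labels = np.where(np.abs(arr) < balanced_band, "balanced", np.where(arr > 0, "surplus", "scarcity"))
    return str(labels) if np.ndim(delta_w) == 0 else labels


def build_balance_table(
    iwr_by_region_year: pd.DataFrame,
    actuals: pd.DataFrame,
    basins: Mapping[str, str] | None = None,
    balanced_band: float = BALANCED_BAND_M3,
    serious_threshold: float = SERIOUS_SCARCITY_M3,
) -> pd.DataFrame:
    """Join required and actual irrigation into a labelled balance table.

    ``iwr_by_region_year`` needs (region_id, year, iwr_m3); ``actuals``
    needs (region_id, year, ia_m3). Regions present in one table but not
    the other raise a ``DataError``.
    """
    for frame, col, name in ((iwr_by_region_year, "iwr_m3", "IWR"), (actuals, "ia_m3", "actuals")):
        missing = {"region_id", "year", col} - set(frame.columns)
        if missing:
            raise DataError(f"{name} table missing column(s): {', '.join(sorted(missing))}")
    df = iwr_by_region_year[["region_id", "year", "iwr_m3"]].merge(
        actuals[["region_id", "year", "ia_m3"]], on=["region_id", "year"], how="outer", indicator=True
    )
    if (df["_merge"] != "both").any():
        bad = df.loc[df["_merge"] != "both", ["region_id", "year"]].head(5).to_dict("records")
        raise DataError(f"IWR and actual-irrigation tables do not align: {bad}")
    df = df.drop(columns="_merge")
    df["delta_w_m3"] = water_balance(df["ia_m3"].to_numpy(float), df["iwr_m3"].to_numpy(float))
    df["qg_m3"] = 0.0
    df["r_m3"] = 0.0
    df["d_m3"] = 0.0
    df["label"] = classify_balance(df["delta_w_m3"].to_numpy(float), balanced_band)
    df["serious_scarcity"] = df["delta_w_m3"] <= serious_threshold
    if basins is not None:
        unmapped = sorted(set(df["region_id"]) - set(basins))
        if unmapped:
            raise DataError(f"region(s) mapped to no basin: {', '.join(unmapped)}")
        df.insert(1, "basin_id", df["region_id"].map(basins))
    return df.sort_values(["region_id", "year"]).reset_index(drop=True)


def basin_balance(balance: pd.DataFrame, balanced_band: float = BALANCED_BAND_M3) -> pd.DataFrame:
    """Aggregate a region balance table to basin-year; ΔW stays additive."""
    if "basin_id" not in balance.columns:
        raise DataError("balance table has no basin_id column")
    out = balance.groupby(["basin_id", "year"], as_index=False)[["ia_m3", "iwr_m3", "delta_w_m3"]].sum()
    out["label"] = classify_balance(out["delta_w_m3"].to_numpy(float), balanced_band)
    return out


def linear_trend(series: Sequence[tuple[float, float]] | pd.DataFrame) -> TrendResult:
    """OLS trend of (year, value) pairs.

    Requires at least three distinct years; exact on noiseless linear input.
    """
    if isinstance(series, pd.DataFrame):
        pairs = series[["year", "value"]].to_numpy(float)
    else:
        pairs = np.asarray(list(series), dtype=float).reshape(-1, 2)
    years, values = pairs[:, 0], pairs[:, 1]
    if len(np.unique(years)) < 3:
        raise InputError("trend requires at least 3 distinct years")
    fit = stats.linregress(years, values)
    return TrendResult(
        slope_per_year=float(fit.slope),
        slope_per_decade=float(fit.slope) * 10.0,
        intercept=float(fit.intercept),
        n_points=len(years),
    )


def trend_table(annual: pd.DataFrame, group_keys: Sequence[str], value_col: str) -> pd.DataFrame:
    """Fit one trend per group of an annual table (columns: group keys, year, value_col)."""
    rows = []
    for keys, sub in annual.groupby(list(group_keys)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        tr = linear_trend(sub.rename(columns={value_col: "value"})[["year", "value"]])
        rows.append(
            dict(zip(group_keys, keys))
            | {
                "variable": value_col,
                "slope_per_year": tr.slope_per_year,
                "slope_per_decade": tr.slope_per_decade,
                "intercept": tr.intercept,
                "n_points": tr.n_points,
            }
        )
    return pd.DataFrame(rows)
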