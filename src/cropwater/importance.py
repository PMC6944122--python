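"""Relative contribution of planting area vs temperature to IWR.

Fits a bagged tree-ensemble regressor (random forest) of annual
irrigation water requirement on planting area and growing-season
temperature per crop, holding out 20% of region-year rows, and scores
predictors by permutation importance on the held-out set: the drop in
predictive skill when one predictor's values are shuffled. Scores are
max-normalized to a 0–100 scale, so the dominant predictor reads 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .errors import DataError, InputError

PREDICTORS = ("area", "temperature")
TRAIN_FRACTION = 0.8


@dataclass(frozen=True)
class ImportanceResult:
    crop: str
    r2_holdout: float
    rmse: float
    mae: float
    importance: Mapping[str, float]  # % scale, max-normalized
    split: tuple[float, float]
    seed: int

    @property
    def ranking(self) -> list[str]:
        return sorted(self.importance, key=self.importance.get, reverse=True)


def build_feature_table(
    demand_table: pd.DataFrame,
    areas: pd.DataFrame,
    regional_temps: pd.DataFrame,
) -> pd.DataFrame:
    """One row per region-year-crop: area, temperature, annual IWR.

    ``regional_temps`` needs (region_id, year, temperature) — typically the
    growing-season mean of the region climate series. A full panel of
    R regions × Y years yields R·Y rows per crop.
    """
    for frame, cols, name in (
        (demand_table, {"region_id", "crop", "year", "iwr_m3"}, "demand table"),
        (areas, {"region_id", "year", "crop", "area_km2"}, "areas table"),
        (regional_temps, {"region_id", "year", "temperature"}, "temperature table"),
    ):
        missing = cols - set(frame.columns)
        if missing:
            raise DataError(f"{name} missing column(s): {', '.join(sorted(missing))}")
    if regional_temps.duplicated(subset=["region_id", "year"]).any():
        raise DataError("duplicated region-year in temperature table")
    if areas.duplicated(subset=["region_id", "year", "crop"]).any():
        raise DataError("duplicated region-year-crop in areas table")

    iwr = demand_table.groupby(["region_id", "year", "crop"], as_index=False)["iwr_m3"].sum()
    df = iwr.merge(areas, on=["region_id", "year", "crop"], validate="one_to_one")
    df = df.merge(regional_temps[["region_id", "year", "temperature"]], on=["region_id", "year"], how="left")
    if df["temperature"].isna().any():
        miss = df.loc[df["temperature"].isna(), ["region_id", "year"]].drop_duplicates().head(5)
        raise DataError(f"missing temperature for region-year(s): {miss.to_dict('records')}")
    df = df.rename(columns={"area_km2": "area", "iwr_m3": "iwr"})
    return df[["region_id", "year", "crop", "area", "temperature", "iwr"]].sort_values(
        ["crop", "region_id", "year"]
    ).reset_index(drop=True)


def fit_importance(
    table: pd.DataFrame,
    crop: str,
    seed: int = 0,
    predictors: Sequence[str] = PREDICTORS,
    n_estimators: int = 300,
    n_repeats: int = 20,
) -> ImportanceResult:
    """Fit the forest for one crop and score predictors on the 20% holdout."""
    sub = table[table["crop"] == crop]
    if len(sub) < 30:
        raise InputError(f"need at least 30 rows for crop {crop!r}, got {len(sub)}")
    X = sub[list(predictors)].to_numpy(float)
    y = sub["iwr"].to_numpy(float)
    if np.ptp(y) == 0:
        raise InputError("response is constant; importance undefined")
    if np.any(np.ptp(X, axis=0) == 0):
        raise InputError("every predictor needs nonzero variance")

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=1.0 - TRAIN_FRACTION, random_state=seed
    )
    model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    model.fit(X_train, y_train)
    y_pred = model.predict(X_test)

    perm = permutation_importance(model, X_test, y_test, n_repeats=n_repeats, random_state=seed)
    raw = np.maximum(perm.importances_mean, 0.0)
    top = raw.max()
    scores = raw / top * 100.0 if top > 0 else raw
    return ImportanceResult(
        crop=crop,
        r2_holdout=float(r2_score(y_test, y_pred)),
        rmse=float(np.sqrt(mean_squared_error(y_test, y_pred))),
        mae=float(mean_absolute_error(y_test, y_pred)),
        importance=dict(zip(predictors, scores.tolist())),
        split=(TRAIN_FRACTION, 1.0 - TRAIN_FRACTION),
        seed=seed,
    )


def importance_report(table: pd.DataFrame, seed: int = 0, crops: Sequence[str] | None = None) -> pd.DataFrame:
    """Fit every crop and tabulate metrics plus normalized scores."""
    crops = sorted(set(table["crop"])) if crops is None else list(crops)
    rows = []
    for crop in crops:
        res = fit_importance(table, crop, seed=seed)
        row = {
            "crop": crop,
            "r2_holdout": res.r2_holdout,
            "rmse": res.rmse,
            "mae": res.mae,
            "seed": seed,
        }
        for pred, score in res.importance.items():
            row[f"importance_{pred}_pct"] = score
        rows.append(row)
    return pd.DataFrame(rows)
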