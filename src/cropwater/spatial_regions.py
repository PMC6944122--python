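"""Station-to-region assignment by the Thiessen-polygon rule.

Thiessen (Voronoi) interpolation assigns every location the value of its
nearest station. On a discrete set of representative cropland cells this is
exactly nearest-station assignment, so the module implements the exhaustive
minimum-distance scan directly: it is deterministic (ties break to the
lexicographically smallest station id) and trivially auditable against the
definition. Regional climate series are cropland-area-weighted means of the
assigned stations' series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, InputError

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class Station:
    """A meteorological station at planar (x, y) in metres, or lon/lat degrees."""

    station_id: str
    x: float
    y: float


@dataclass(frozen=True)
class RegionGeometry:
    """Representative cropland cells of one region with area weights."""

    region_id: str
    basin_id: str
    cells: tuple[tuple[float, float, float], ...]  # (x, y, weight)

    def __post_init__(self):
        if not self.cells:
            raise InputError(f"region {self.region_id} has no cells")
        weights = np.array([c[2] for c in self.cells], dtype=float)
        if np.any(weights < 0) or weights.sum() <= 0:
            raise InputError(f"region {self.region_id} weights must be >= 0 with positive sum")

    @property
    def xy(self) -> np.ndarray:
        return np.array([(c[0], c[1]) for c in self.cells], dtype=float)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c[2] for c in self.cells], dtype=float)


def _distance_matrix(cells: np.ndarray, sxy: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        diff = cells[:, None, :] - sxy[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "great_circle":
        lon1 = np.deg2rad(cells[:, None, 0])
        lat1 = np.deg2rad(cells[:, None, 1])
        lon2 = np.deg2rad(sxy[None, :, 0])
        lat2 = np.deg2rad(sxy[None, :, 1])
        a = (
            np.sin((lat2 - lat1) / 2) ** 2
            + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
        )
        return 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    raise InputError(f"unknown metric {metric!r}")


def thiessen_assign(
    stations: Sequence[Station] | pd.DataFrame,
    cells: Iterable[tuple[float, float]],
    metric: str = "euclidean",
) -> np.ndarray:
    """Nearest station id for every cell.

    ``metric`` is ``euclidean`` for projected planar coordinates (metres) or
    ``great_circle`` when (x, y) are (lon, lat) degrees. Distance ties break
    to the smallest station id.
    """
    if isinstance(stations, pd.DataFrame):
        stations = [Station(str(r.station_id), float(r.x), float(r.y)) for r in stations.itertuples()]
    stations = list(stations)
    if not stations:
        raise InputError("at least one station is required")
    ids = [s.station_id for s in stations]
    if len(set(ids)) != len(ids):
        raise InputError("station ids must be unique")
    order = np.argsort(np.array(ids, dtype=object))
    ids_sorted = np.array(ids, dtype=object)[order]
    sxy = np.array([(s.x, s.y) for s in stations], dtype=float)[order]
    cell_arr = np.asarray(list(cells), dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(cell_arr)) or not np.all(np.isfinite(sxy)):
        raise InputError("coordinates must be finite")
    if cell_arr.shape[0] == 0:
        return np.array([], dtype=object)
    d = _distance_matrix(cell_arr, sxy, metric)
    # argmin returns the first minimum; stations are ordered by id, so exact
    # distance ties resolve to the lexicographically smallest id
    return ids_sorted[np.argmin(d, axis=1)]


def region_station_weights(
    region: RegionGeometry, cell_stations: Sequence[str]
) -> pd.Series:
    """Total cropland weight per assigned station, normalized to sum 1."""
    if len(cell_stations) != len(region.cells):
        raise InputError("one assigned station per region cell is required")
    w = pd.Series(region.weights, index=pd.Index(cell_stations, name="station_id"))
    w = w.groupby(level=0).sum()
    return w / w.sum()


def region_climate(
    cell_stations: Sequence[str],
    station_series: pd.DataFrame,
    region: RegionGeometry,
    value_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Weighted monthly series for one region.

    ``station_series`` is long-form with columns (station_id, year, month,
    value columns). Every station assigned to the region must cover every
    (year, month) present in the table; a gap raises a ``DataError`` naming
    the station and month.
    """
    needed = {"station_id", "year", "month"}
    if not needed <= set(station_series.columns):
        raise DataError("station series needs columns station_id, year, month")
    if value_columns is None:
        value_columns = [c for c in station_series.columns if c not in needed]
    weights = region_station_weights(region, cell_stations)

    periods = station_series[["year", "month"]].drop_duplicates()
    sub = station_series[station_series["station_id"].isin(weights.index)]
    counts = sub.groupby("station_id")[["year"]].count()["year"]
    for sid in weights.index:
        have = sub[sub["station_id"] == sid][["year", "month"]]
        if len(have) < len(periods):
            missing = periods.merge(have, how="left", indicator=True, on=["year", "month"])
            gap = missing[missing["_merge"] == "left_only"].iloc[0]
            raise DataError(
                f"station {sid} assigned to region {region.region_id} is missing "
                f"{int(gap['year'])}-{int(gap['month']):02d}"
            )

    sub = sub.copy()
    sub["_w"] = sub["station_id"].map(weights)
    out = {}
    for col in value_columns:
        weighted = sub.assign(_wv=sub["_w"] * sub[col])
        grouped = weighted.groupby(["year", "month"])
        out[col] = grouped["_wv"].sum() / grouped["_w"].sum()
    result = pd.DataFrame(out).reset_index()
    result.insert(0, "region_id", region.region_id)
    result.insert(1, "basin_id", region.basin_id)
    return result.sort_values(["year", "month"]).reset_index(drop=True)
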