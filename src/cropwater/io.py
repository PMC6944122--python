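"""Validated delimited-text readers and writers for every pipeline table.

All interchange is plain CSV with documented headers; units are declared in
the column names (``area_km2``, ``ia_m3`` / ``ia_billion_m3``, mm for
depths). Readers raise :class:`~cropwater.errors.DataError` naming the
offending column or rows, so silent data loss is impossible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import DataError
from .meteo_et0 import validate_station_table
from .spatial_regions import RegionGeometry

DELIMITER = ","


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, sep=DELIMITER)
    return path


def _read(path: str | Path, required: Sequence[str], name: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=DELIMITER)
    except FileNotFoundError:
        raise DataError(f"{name} file not found: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{name} table {path} missing column(s): {', '.join(missing)}")
    return df


def read_station_monthly(path: str | Path) -> pd.DataFrame:
    """Station monthly meteorology; validates schema and physical invariants."""
    from .meteo_et0 import STATION_COLUMNS

    df = _read(path, STATION_COLUMNS, "station meteorology")
    validate_station_table(df)
    return df


def read_stations(path: str | Path) -> pd.DataFrame:
    """Station locations with planar coordinates (station_id, x, y, ...)."""
    df = _read(path, ("station_id", "x", "y"), "stations")
    if df["station_id"].duplicated().any():
        raise DataError("duplicate station ids in stations table")
    return df


def read_regions(path: str | Path) -> tuple[list[RegionGeometry], dict[str, str]]:
    """Region cell table (region_id, basin_id, x, y, weight) → geometries + basin map."""
    df = _read(path, ("region_id", "basin_id", "x", "y", "weight"), "regions")
    geoms = []
    basins: dict[str, str] = {}
    for (rid, bid), sub in df.groupby(["region_id", "basin_id"], sort=True):
        geoms.append(
            RegionGeometry(
                region_id=str(rid),
                basin_id=str(bid),
                cells=tuple((float(r.x), float(r.y), float(r.weight)) for r in sub.itertuples()),
            )
        )
        basins[str(rid)] = str(bid)
    return geoms, basins


def write_regions(geoms: Sequence[RegionGeometry], path: str | Path) -> Path:
    rows = [
        {"region_id": g.region_id, "basin_id": g.basin_id, "x": x, "y": y, "weight": w}
        for g in geoms
        for x, y, w in g.cells
    ]
    return write_table(pd.DataFrame(rows), path)


def read_crop_areas(path: str | Path) -> pd.DataFrame:
    df = _read(path, ("region_id", "year", "crop", "area_km2"), "crop areas")
    if (df["area_km2"] < 0).any():
        raise DataError("negative crop area")
    return df


def read_efficiency(path: str | Path) -> pd.DataFrame:
    df = _read(path, ("region_id", "ie"), "irrigation efficiency")
    bad = df[(df["ie"] <= 0) | (df["ie"] > 1)]
    if len(bad):
        raise DataError(f"irrigation efficiency outside (0, 1] for: {sorted(bad['region_id'])}")
    return df


def read_actuals(path: str | Path) -> pd.DataFrame:
    """Actual irrigation per region-year; accepts ia_m3 or ia_billion_m3."""
    df = _read(path, ("region_id", "year"), "actual irrigation")
    if "ia_m3" in df.columns:
        pass
    elif "ia_billion_m3" in df.columns:
        df = df.assign(ia_m3=df["ia_billion_m3"] * 1e9)
    else:
        raise DataError("actual irrigation table needs an ia_m3 or ia_billion_m3 column")
    if (df["ia_m3"] < 0).any():
        raise DataError("negative actual irrigation")
    return df[["region_id", "year", "ia_m3"]]
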