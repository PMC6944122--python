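"""Effective precipitation, CWR/IWR arithmetic and aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropwater.demand import (
    XINJIANG_IE,
    XINJIANG_IE_MEAN,
    aggregate_iwr,
    build_demand_table,
    crop_et,
    crop_share,
    crop_water_requirement,
    effective_precip,
    irrigation_water_requirement,
)
from cropwater.errors import DataError, InputError


def test_effective_precip_values():
    assert effective_precip(0.0) == 0.0
    assert effective_precip(100.0) == pytest.approx(52.0, abs=1e-12)
    # annual-mean precipitation of the driest basin in the study region
    assert effective_precip(41.62) == pytest.approx(21.6424, abs=1e-10)
    with pytest.raises(InputError):
        effective_precip(-1.0)


def test_crop_et_is_exact_product():
    assert crop_et(0.0, 150.0) == 0.0
    assert crop_et(1.0, 150.0) == 150.0
    assert crop_et(1.2, 200.0) == pytest.approx(240.0, abs=0)


def test_crop_water_requirement_clamp_and_raw():
    assert crop_water_requirement(240.0, 40.0) == pytest.approx(200.0)
    assert crop_water_requirement(10.0, 30.0) == 0.0
    assert crop_water_requirement(10.0, 30.0, clamp=False) == pytest.approx(-20.0)


def test_irrigation_water_requirement_units():
    assert irrigation_water_requirement(1.0, 500.0, 1.0) == pytest.approx(500_000.0)
    assert irrigation_water_requirement(1.0, 500.0, XINJIANG_IE_MEAN) == pytest.approx(735_294.1176470588)
    assert irrigation_water_requirement(0.0, 500.0, 0.7) == 0.0
    with pytest.raises(InputError):
        irrigation_water_requirement(1.0, 500.0, 0.0)
    with pytest.raises(InputError):
        irrigation_water_requirement(1.0, 500.0, 1.5)


@settings(max_examples=100, derandomize=True)
@given(
    area=st.floats(min_value=0, max_value=1e4),
    cwr=st.floats(min_value=0, max_value=1500),
    ie=st.floats(min_value=0.05, max_value=1.0),
    d_ie=st.floats(min_value=0.0, max_value=0.5),
)
def test_iwr_monotonicity(area, cwr, ie, d_ie):
    base = irrigation_water_requirement(area, cwr, ie)
    assert irrigation_water_requirement(area, cwr, min(ie + d_ie, 1.0)) <= base + 1e-9
    assert irrigation_water_requirement(area * 2, cwr, ie) == pytest.approx(2 * base)
    assert irrigation_water_requirement(area, cwr + 10, ie) >= base


def _demand_fixture():
    rows = []
    values = {
        ("R1", "wheat", 5): 10.0, ("R1", "wheat", 6): 20.0,
        ("R1", "cotton", 5): 30.0, ("R1", "cotton", 6): 40.0,
        ("R2", "wheat", 5): 5.0, ("R2", "wheat", 6): 15.0,
        ("R2", "cotton", 5): 25.0, ("R2", "cotton", 6): 35.0,
    }
    for (region, crop, month), iwr in values.items():
        rows.append(
            {
                "region_id": region,
                "basin_id": "B1" if region == "R1" else "B2",
                "crop": crop,
                "year": 2010,
                "month": month,
                "iwr_m3": iwr * 1e6,
            }
        )
    return pd.DataFrame(rows)


def test_aggregate_matches_brute_force_sums():
    df = _demand_fixture()
    by_crop = aggregate_iwr(df, by=("crop",)).set_index("crop")["iwr_m3"]
    for crop in ("wheat", "cotton"):
        expected = df[df["crop"] == crop]["iwr_m3"].to_numpy().sum()
        assert by_crop[crop] == pytest.approx(expected, rel=1e-15)
    single = aggregate_iwr(df.iloc[[0]], by=("region", "crop"))
    assert single["iwr_m3"].iloc[0] == df["iwr_m3"].iloc[0]


def test_aggregate_partition_invariance():
    df = _demand_fixture()
    grand = df["iwr_m3"].sum()
    by_basin = aggregate_iwr(df, by=("basin",))
    assert by_basin["iwr_m3"].sum() == pytest.approx(grand, rel=1e-15)
    by_region = aggregate_iwr(df, by=("region",))
    assert by_region["iwr_m3"].sum() == pytest.approx(grand, rel=1e-15)


def test_crop_share_cases():
    df = _demand_fixture()
    only_wheat = df[df["crop"] == "wheat"]
    assert crop_share(only_wheat, "wheat", 2010) == pytest.approx(100.0)

    three = pd.DataFrame(
        {"region_id": "R", "crop": ["a", "b", "c"], "year": 2000, "iwr_m3": [1.0, 1.0, 1.0]}
    )
    assert crop_share(three, "a", 2000) == pytest.approx(100.0 / 3.0)

    with pytest.raises(DataError):
        crop_share(df.assign(iwr_m3=0.0), "wheat", 2010)


def test_crop_share_headline_ratio():
    """26.39 of 38.99 billion m3 is 67.68% at two decimals."""
    df = pd.DataFrame(
        {
            "region_id": "X",
            "crop": ["cotton", "other"],
            "year": 2017,
            "iwr_m3": [26.39e9, (38.99 - 26.39) * 1e9],
        }
    )
    assert round(crop_share(df, "cotton", 2017), 2) == 67.68


def _mini_inputs(area_scale=1.0):
    climate = pd.DataFrame(
        {
            "region_id": ["R1"] * 2 + ["R2"] * 2,
            "year": 2010,
            "month": [6, 7] * 2,
            "et0_month": [180.0, 200.0, 150.0, 170.0],
            "precip": [10.0, 5.0, 60.0, 80.0],
        }
    )
    kc = pd.DataFrame(
        {
            "region_id": ["R1"] * 2 + ["R2"] * 2,
            "crop": "cotton",
            "year": 2010,
            "month": [6, 7] * 2,
            "kc": [1.0, 1.2, 1.0, 1.2],
        }
    )
    areas = pd.DataFrame(
        {"region_id": ["R1", "R2"], "year": 2010, "crop": "cotton", "area_km2": [100.0 * area_scale, 50.0 * area_scale]}
    )
    eff = {"R1": 0.7, "R2": 0.6}
    basins = {"R1": "B1", "R2": "B2"}
    return climate, kc, areas, eff, basins


def test_build_demand_table_values_and_units():
    climate, kc, areas, eff, basins = _mini_inputs()
    table = build_demand_table(climate, kc, areas, eff, basins)
    row = table[(table.region_id == "R1") & (table.month == 6)].iloc[0]
    assert row["pe"] == pytest.approx(5.2)
    assert row["etc"] == pytest.approx(180.0)
    assert row["cwr"] == pytest.approx(174.8)
    assert row["iwr_m3"] == pytest.approx(100.0 * 174.8 * 1000 / 0.7)


def test_build_demand_table_unit_scaling_in_area():
    climate, kc, areas, eff, basins = _mini_inputs()
    base = build_demand_table(climate, kc, areas, eff, basins)
    scaled = build_demand_table(*_mini_inputs(area_scale=3.0)[:3], eff, basins)
    np.testing.assert_allclose(scaled["iwr_m3"].to_numpy(), 3.0 * base["iwr_m3"].to_numpy(), rtol=1e-15)


def test_build_demand_table_clamp_raises_total():
    climate, kc, areas, eff, basins = _mini_inputs()
    clamped = build_demand_table(climate, kc, areas, eff, basins, clamp=True)
    raw = build_demand_table(climate, kc, areas, eff, basins, clamp=False)
    assert clamped["cwr"].sum() >= raw["cwr"].sum()


def test_build_demand_table_missing_efficiency_fails_loudly():
    climate, kc, areas, _, basins = _mini_inputs()
    with pytest.raises(DataError, match="R2"):
        build_demand_table(climate, kc, areas, {"R1": 0.7}, basins)


def test_build_demand_table_missing_basin_fails():
    climate, kc, areas, eff, _ = _mini_inputs()
    with pytest.raises(DataError, match="R2"):
        build_demand_table(climate, kc, areas, eff, {"R1": "B1"})


def test_shipped_efficiency_fixture():
    assert len(XINJIANG_IE) == 15
    assert all(0 < v <= 1 for v in XINJIANG_IE.values())
    assert max(XINJIANG_IE, key=XINJIANG_IE.get) in {"Karamay", "Turpan"}
    assert min(XINJIANG_IE.values()) == 0.60
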