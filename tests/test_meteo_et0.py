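"""Unit and property tests for the Penman-Monteith ET0 stack."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropwater.errors import DataError, InputError
from cropwater.meteo_et0 import (
    Et0Inputs,
    daylight_hours,
    et0_penman_monteith,
    extraterrestrial_radiation,
    net_radiation,
    pressure_from_elevation,
    psychrometric_gamma,
    saturation_vapor_pressure,
    slope_delta,
    soil_heat_flux_edge,
    soil_heat_flux_monthly,
    station_et0_series,
    vapor_pressure_terms,
    wind_at_2m,
)


@pytest.mark.parametrize(
    "t, expected",
    [(0.0, 0.6108), (20.0, 2.3382813), (30.0, 4.2430651)],
)
def test_saturation_vapor_pressure_values(t, expected):
    assert saturation_vapor_pressure(t) == pytest.approx(expected, rel=1e-6)


def test_saturation_vapor_pressure_rejects_bad_input():
    with pytest.raises(InputError):
        saturation_vapor_pressure(float("nan"))
    with pytest.raises(InputError):
        saturation_vapor_pressure(-240.0)


@settings(max_examples=100, derandomize=True)
@given(st.floats(min_value=-40, max_value=50), st.floats(min_value=0.01, max_value=5))
def test_saturation_vapor_pressure_strictly_increasing(t, dt):
    assert saturation_vapor_pressure(t + dt) > saturation_vapor_pressure(t)


@pytest.mark.parametrize(
    "t_max, t_min, rh, e_s, e_a",
    [
        (20.0, 20.0, 100.0, 2.3382813, 2.3382813),
        (30.0, 10.0, 50.0, 2.7355138, 1.3677569),
        (30.0, 10.0, 0.0, 2.7355138, 0.0),
    ],
)
def test_vapor_pressure_terms(t_max, t_min, rh, e_s, e_a):
    got_es, got_ea = vapor_pressure_terms(t_max, t_min, rh)
    assert got_es == pytest.approx(e_s, rel=1e-6)
    assert got_ea == pytest.approx(e_a, rel=1e-6, abs=1e-12)


def test_vapor_pressure_terms_rejects_bad_humidity():
    with pytest.raises(InputError):
        vapor_pressure_terms(20, 10, 120)
    with pytest.raises(InputError):
        vapor_pressure_terms(10, 20, 50)


def test_slope_delta_values_and_monotonicity():
    assert slope_delta(20.0) == pytest.approx(0.1447402, rel=1e-6)
    assert slope_delta(30.0) == pytest.approx(0.2433625, rel=1e-6)
    assert slope_delta(30.0) > slope_delta(20.0)


def test_pressure_and_gamma():
    assert pressure_from_elevation(0.0) == pytest.approx(101.3, rel=1e-12)
    assert pressure_from_elevation(1000.0) == pytest.approx(90.0246200, rel=1e-6)
    assert psychrometric_gamma(101.3) == pytest.approx(0.0673645, rel=1e-9)
    with pytest.raises(InputError):
        psychrometric_gamma(0.0)


def test_wind_profile_conversion():
    assert wind_at_2m(3.0, 2.0) == pytest.approx(3.0, rel=1e-3)
    assert wind_at_2m(3.0, 10.0) == pytest.approx(2.2438532, rel=1e-6)
    assert wind_at_2m(0.0, 7.0) == 0.0
    with pytest.raises(InputError):
        wind_at_2m(3.0, 0.05)


def test_net_radiation_hand_calculation():
    """Step-by-step FAO-56 evaluation at 44N in July, frozen independently."""
    rn = net_radiation(44.0, 7, 30.0, 18.0, 1.8, 11.0)
    assert rn == pytest.approx(14.8850659, rel=1e-6)


def test_net_radiation_cloudiness_monotonicity():
    t = 25.0
    e_a = saturation_vapor_pressure(t)
    n_max = daylight_hours(44.0, 7)
    overcast = net_radiation(44.0, 7, t, t, e_a, 0.0)
    clear = net_radiation(44.0, 7, t, t, e_a, n_max)
    assert overcast < clear


def test_extraterrestrial_radiation_hemispheric_symmetry():
    """Opposite hemisphere six months apart sees the same solar geometry.

    The inverse-distance factor dr is removed first: perihelion falls in
    January, so raw Ra is ~6% asymmetric for physical (orbital) reasons.
    """
    dr = lambda j: 1 + 0.033 * np.cos(2 * np.pi * j / 365)
    north_july = extraterrestrial_radiation(44.0, 7) / dr(196)
    south_january = extraterrestrial_radiation(-44.0, 1) / dr(15)
    assert south_january == pytest.approx(north_july, rel=0.01)


def test_polar_latitude_rejected():
    with pytest.raises(InputError):
        extraterrestrial_radiation(70.0, 6)


def test_soil_heat_flux():
    assert soil_heat_flux_monthly(15.0, 15.0) == 0.0
    assert soil_heat_flux_monthly(10.0, 20.0) == pytest.approx(0.7)
    assert soil_heat_flux_edge(15.0, 10.0) == pytest.approx(0.7)
    assert soil_heat_flux_monthly(20.0, 10.0) < 0  # cooling


def _inputs(**kw):
    base = dict(delta=0.145, r_n=20.0, g=0.3, gamma=0.0674, t=20.0, u2=2.0, e_s=2.34, e_a=1.40)
    base.update(kw)
    return Et0Inputs(**base)


def test_penman_monteith_zero_when_both_terms_vanish():
    assert et0_penman_monteith(_inputs(r_n=5.0, g=5.0, e_a=2.34)) == 0.0


def test_penman_monteith_hand_calculation():
    assert et0_penman_monteith(_inputs()) == pytest.approx(6.0204380, rel=1e-6)


def test_penman_monteith_increases_with_vapor_deficit():
    low = et0_penman_monteith(_inputs())
    high = et0_penman_monteith(_inputs(e_a=2.34 - 2 * (2.34 - 1.40)))
    assert high > low


def test_penman_monteith_rejects_nonpositive_gamma_delta():
    with pytest.raises(InputError):
        et0_penman_monteith(_inputs(gamma=0.0))
    with pytest.raises(InputError):
        et0_penman_monteith(_inputs(delta=-0.1))


def test_penman_monteith_floor():
    # Rn < G with zero deficit drives the rate negative; the floor holds it at 0
    neg = _inputs(r_n=0.0, g=3.0, e_a=2.34)
    assert et0_penman_monteith(neg) == 0.0
    assert et0_penman_monteith(neg, floor=False) < 0.0


def _monthly_frame(n_months=12, station="S1", t_mean=20.0, rh=50.0, year=2005):
    months = np.arange(1, n_months + 1)
    return pd.DataFrame(
        {
            "station_id": station,
            "lat": 42.0,
            "lon": 85.0,
            "elevation": 600.0,
            "year": year,
            "month": months,
            "t_max": t_mean + 6.0,
            "t_min": t_mean - 6.0,
            "t_mean": t_mean,
            "precip": 10.0,
            "wind_speed": 2.5,
            "anemometer_height": 10.0,
            "pressure": np.nan,
            "rel_humidity": rh,
            "sunshine_hours": 8.0,
        }
    )


def test_station_series_identical_conditions_give_equal_rates():
    """Determinism: the same July meteorology repeated over years yields one rate."""
    frames = [_monthly_frame(year=y) for y in range(2001, 2013)]
    july = pd.concat(frames, ignore_index=True).query("month == 7").reset_index(drop=True)
    out = station_et0_series(july)
    assert len(out) == 12
    assert out["et0_daily"].nunique() == 1


def test_station_series_monthly_totals_scale_by_month_length():
    out = station_et0_series(_monthly_frame())
    assert len(out) == 12
    expected = out["et0_daily"].to_numpy() * np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
    np.testing.assert_allclose(out["et0_month"].to_numpy(), expected, rtol=0, atol=0)


def test_station_series_leap_year_february():
    out = station_et0_series(_monthly_frame(year=2004))
    feb = out[out["month"] == 2].iloc[0]
    assert feb["et0_month"] == pytest.approx(feb["et0_daily"] * 29, abs=0)


def test_station_series_hot_dry_station_exceeds_cool_wet():
    hot = _monthly_frame(station="A", t_mean=25.0, rh=30.0)
    cool = _monthly_frame(station="B", t_mean=10.0, rh=80.0)
    out = station_et0_series(pd.concat([hot, cool], ignore_index=True))
    annual = out.groupby("station_id")["et0_month"].sum()
    assert annual["A"] > annual["B"]


def test_station_series_empty_and_errors():
    empty = _monthly_frame().iloc[0:0]
    assert station_et0_series(empty).empty

    dup = pd.concat([_monthly_frame(), _monthly_frame()], ignore_index=True)
    with pytest.raises(DataError, match="duplicate"):
        station_et0_series(dup)

    with pytest.raises(DataError, match="t_mean"):
        station_et0_series(_monthly_frame().drop(columns=["t_mean"]))


def test_station_series_drops_incomplete_months():
    frame = _monthly_frame()
    frame.loc[3, "rel_humidity"] = np.nan
    out = station_et0_series(frame)
    assert len(out) == 11


@settings(max_examples=200, derandomize=True)
@given(
    delta=st.floats(min_value=0.01, max_value=0.5),
    r_n=st.floats(min_value=-5, max_value=35),
    g=st.floats(min_value=-3, max_value=3),
    gamma=st.floats(min_value=0.04, max_value=0.09),
    t=st.floats(min_value=-20, max_value=45),
    u2=st.floats(min_value=0, max_value=10),
    e_s=st.floats(min_value=0.1, max_value=9),
    frac=st.floats(min_value=0, max_value=1),
)
def test_penman_monteith_floored_rate_non_negative(delta, r_n, g, gamma, t, u2, e_s, frac):
    value = et0_penman_monteith(
        Et0Inputs(delta=delta, r_n=r_n, g=g, gamma=gamma, t=t, u2=u2, e_s=e_s, e_a=e_s * frac)
    )
    assert value >= 0.0
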