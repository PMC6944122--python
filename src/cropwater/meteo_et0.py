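"""Reference evapotranspiration (ET0) from monthly station meteorology.

Implements the FAO-56 Penman-Monteith combination equation

    ET0 = [0.408 Δ (Rn − G) + γ · 900/(T+273) · u2 · (es − ea)]
          / [Δ + γ (1 + 0.34 u2)]

with ET0 in mm/day, together with the standard FAO-56 sub-term formulas:
saturation vapor pressure e°(T), slope of the vapor-pressure curve Δ,
psychrometric constant γ from air pressure (or pressure from elevation),
logarithmic wind-profile conversion to 2 m, extraterrestrial and net
radiation from latitude, month and sunshine hours, and the monthly soil
heat flux G from the temperature of adjacent months.

Computation cadence is monthly: all inputs are monthly means, ET0 is a
daily rate from those means, and monthly totals scale the rate by the
calendar length of the month (29 days for February in leap years). The
representative day for solar geometry is the 15th of each month.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataError, InputError

log = logging.getLogger(__name__)

#: Solar constant, MJ m-2 min-1.
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1.
STEFAN_BOLTZMANN = 4.903e-9
#: Reference-surface albedo (well-watered clipped grass).
ALBEDO = 0.23
#: Angstrom regression coefficients relating sunshine fraction to Rs/Ra.
ANGSTROM_AS = 0.25
ANGSTROM_BS = 0.50
#: Clear-sky shortwave fraction Rso/Ra.
CLEAR_SKY_FRACTION = 0.75
#: Anemometer height assumed when a station does not report one, m.
DEFAULT_ANEMOMETER_HEIGHT = 10.0

#: Day of year of the 15th of each month (non-leap calendar).
MONTH_MID_DOY = (15, 46, 74, 105, 135, 166, 196, 227, 258, 288, 319, 349)

#: Columns a station monthly table must provide.
STATION_COLUMNS = (
    "station_id",
    "lat",
    "lon",
    "elevation",
    "year",
    "month",
    "t_max",
    "t_min",
    "t_mean",
    "precip",
    "wind_speed",
    "anemometer_height",
    "pressure",
    "rel_humidity",
    "sunshine_hours",
)

#: Numeric fields ET0 cannot be computed without (pressure and anemometer
#: height have documented fallbacks and may be missing).
_ET0_REQUIRED = (
    "lat",
    "elevation",
    "t_max",
    "t_min",
    "t_mean",
    "wind_speed",
    "rel_humidity",
    "sunshine_hours",
)


def _as_float(x, name: str):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InputError(f"{name} must be finite, got {x!r}")
    return arr if arr.ndim else float(arr)


def saturation_vapor_pressure(t):
    """Saturation vapor pressure e°(T) in kPa at air temperature ``t`` (°C).

    e°(T) = 0.6108 · exp(17.27 T / (T + 237.3)); strictly increasing in T.
    """
    t = _as_float(t, "t")
    if np.any(np.asarray(t) <= -237.3):
        raise InputError("temperature must exceed -237.3 degC")
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def vapor_pressure_terms(t_max, t_min, rel_humidity):
    """Saturated and actual vapor pressure (es, ea) in kPa.

    es is the mean of e° at the monthly maximum and minimum temperature;
    ea applies the mean relative humidity to es.
    """
    t_max = _as_float(t_max, "t_max")
    t_min = _as_float(t_min, "t_min")
    rh = _as_float(rel_humidity, "rel_humidity")
    if np.any(np.asarray(t_min) > np.asarray(t_max)):
        raise InputError("t_min must not exceed t_max")
    if np.any(np.asarray(rh) < 0) or np.any(np.asarray(rh) > 100):
        raise InputError("rel_humidity must lie in [0, 100] %")
    e_s = (saturation_vapor_pressure(t_max) + saturation_vapor_pressure(t_min)) / 2.0
    e_a = rh / 100.0 * e_s
    return e_s, e_a


def slope_delta(t):
    """Slope Δ of the saturation vapor-pressure curve, kPa/°C.

    Δ = 4098 · e°(T) / (T + 237.3)².
    """
    t = _as_float(t, "t")
    return 4098.0 * saturation_vapor_pressure(t) / (t + 237.3) ** 2


def pressure_from_elevation(z):
    """Mean atmospheric pressure (kPa) at elevation ``z`` (m), barometric formula."""
    z = _as_float(z, "z")
    if np.any(np.asarray(z) < -100):
        raise InputError("elevation below -100 m is not supported")
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def psychrometric_gamma(pressure):
    """Psychrometric constant γ (kPa/°C) from air pressure (kPa)."""
    p = _as_float(pressure, "pressure")
    if np.any(np.asarray(p) <= 0):
        raise InputError("pressure must be positive")
    return 0.665e-3 * p


def wind_at_2m(u_z, z):
    """Convert wind speed measured at height ``z`` (m) to 2 m, log profile.

    u2 = u_z · 4.87 / ln(67.8 z − 5.42); identity (to 0.1%) at z = 2.
    """
    u_z = _as_float(u_z, "u_z")
    z = _as_float(z, "z")
    if np.any(np.asarray(z) <= 0.08):
        raise InputError("anemometer height must exceed 0.08 m")
    if np.any(np.asarray(u_z) < 0):
        raise InputError("wind speed must be non-negative")
    return u_z * 4.87 / np.log(67.8 * z - 5.42)


def _solar_geometry(lat, month):
    lat = _as_float(lat, "lat")
    month_arr = np.asarray(month)
    if np.any(month_arr < 1) or np.any(month_arr > 12):
        raise InputError("month must lie in 1..12")
    if np.any(np.abs(np.asarray(lat)) >= 66.5):
        raise InputError("polar latitudes (|lat| >= 66.5) are unsupported")
    j = np.take(MONTH_MID_DOY, month_arr - 1)
    phi = np.deg2rad(lat)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    dec = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(dec), -1.0, 1.0))
    return phi, dr, dec, ws


def extraterrestrial_radiation(lat, month):
    """Extraterrestrial radiation Ra (MJ m-2 day-1) for the month's mid-day."""
    phi, dr, dec, ws = _solar_geometry(lat, month)
    ra = (
        24.0 * 60.0 / np.pi
        * SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(dec) + np.cos(phi) * np.cos(dec) * np.sin(ws))
    )
    return ra


def daylight_hours(lat, month):
    """Maximum possible sunshine duration N (h/day) for the month's mid-day."""
    _, _, _, ws = _solar_geometry(lat, month)
    return 24.0 / np.pi * ws


def net_radiation(
    lat,
    month,
    t_max,
    t_min,
    e_a,
    sunshine_hours,
    angstrom_as: float = ANGSTROM_AS,
    angstrom_bs: float = ANGSTROM_BS,
    albedo: float = ALBEDO,
    clear_sky_fraction: float = CLEAR_SKY_FRACTION,
):
    """Net surface radiation Rn (MJ m-2 day-1).

    Shortwave: Rs = (as + bs·n/N)·Ra, Rns = (1 − albedo)·Rs.
    Longwave: Stefan-Boltzmann on the mean of Tmax⁴ and Tmin⁴ (Kelvin) with
    the vapor-pressure (0.34 − 0.14 √ea) and cloudiness (1.35 Rs/Rso − 0.35)
    correction factors, Rso = clear_sky_fraction · Ra.
    """
    t_max = _as_float(t_max, "t_max")
    t_min = _as_float(t_min, "t_min")
    e_a = _as_float(e_a, "e_a")
    n = _as_float(sunshine_hours, "sunshine_hours")
    if np.any(np.asarray(e_a) < 0):
        raise InputError("actual vapor pressure must be non-negative")
    ra = extraterrestrial_radiation(lat, month)
    n_max = daylight_hours(lat, month)
    n_arr = np.asarray(n)
    if np.any(n_arr < 0) or np.any(n_arr > np.asarray(n_max) + 1e-6):
        raise InputError("sunshine hours must lie in [0, daylight hours]")
    sun_frac = np.clip(n / n_max, 0.0, 1.0)
    rs = (angstrom_as + angstrom_bs * sun_frac) * ra
    rso = clear_sky_fraction * ra
    rns = (1.0 - albedo) * rs
    tk4 = ((t_max + 273.16) ** 4 + (t_min + 273.16) ** 4) / 2.0
    rnl = (
        STEFAN_BOLTZMANN
        * tk4
        * (0.34 - 0.14 * np.sqrt(e_a))
        * (1.35 * np.clip(rs / rso, 0.0, 1.0) - 0.35)
    )
    return rns - rnl


def soil_heat_flux_monthly(t_prev, t_next):
    """Monthly soil heat flux G (MJ m-2 day-1) from adjacent months' means.

    G = 0.07 (T_next − T_prev), the centered monthly FAO-56 form.
    """
    t_prev = _as_float(t_prev, "t_prev")
    t_next = _as_float(t_next, "t_next")
    return 0.07 * (t_next - t_prev)


def soil_heat_flux_edge(t_curr, t_prev):
    """One-sided monthly soil heat flux, G = 0.14 (T_i − T_{i−1})."""
    t_curr = _as_float(t_curr, "t_curr")
    t_prev = _as_float(t_prev, "t_prev")
    return 0.14 * (t_curr - t_prev)


@dataclass(frozen=True)
class Et0Inputs:
    """The complete Penman-Monteith term set for one station-month.

    delta: kPa/°C; r_n, g: MJ m-2 day-1; gamma: kPa/°C; t: °C (mean);
    u2: m/s at 2 m; e_s, e_a: kPa.
    """

    delta: float
    r_n: float
    g: float
    gamma: float
    t: float
    u2: float
    e_s: float
    e_a: float

    def validate(self) -> None:
        if not all(
            np.isfinite(v)
            for v in (self.delta, self.r_n, self.g, self.gamma, self.t, self.u2, self.e_s, self.e_a)
        ):
            raise InputError("all Penman-Monteith terms must be finite")
        if self.delta <= 0 or self.gamma <= 0:
            raise InputError("delta and gamma must be positive")
        if self.e_a < 0 or self.e_s < self.e_a:
            raise InputError("vapor pressures must satisfy 0 <= e_a <= e_s")
        if self.u2 < 0:
            raise InputError("u2 must be non-negative")


@dataclass(frozen=True)
class Et0Result:
    """Daily-rate and monthly-total reference evapotranspiration."""

    station_id: str
    year: int
    month: int
    et0_daily: float
    et0_month: float


def _pm_rate(delta, r_n, g, gamma, t, u2, e_s, e_a):
    """Raw (unfloored) Penman-Monteith daily rate, mm/day."""
    num = 0.408 * delta * (r_n - g) + gamma * 900.0 / (t + 273.0) * u2 * (e_s - e_a)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return num / den


def et0_penman_monteith(inputs: Et0Inputs, floor: bool = True) -> float:
    """Daily reference evapotranspiration (mm/day) for one term set.

    Negative rates (possible when Rn < G with no vapor deficit) are floored
    at zero unless ``floor=False``.
    """
    inputs.validate()
    rate = _pm_rate(
        inputs.delta, inputs.r_n, inputs.g, inputs.gamma,
        inputs.t, inputs.u2, inputs.e_s, inputs.e_a,
    )
    if floor:
        rate = max(rate, 0.0)
    return float(rate)


def days_in_month(year: int, month: int) -> int:
    return calendar.monthrange(int(year), int(month))[1]


def _soil_heat_flux_series(t_mean: np.ndarray) -> np.ndarray:
    """G for a chronologically ordered monthly series of one station.

    Interior months use the centered form; the last month falls back to the
    one-sided 0.14(T_i − T_{i−1}) and the first month to its mirror
    0.14(T_{i+1} − T_i). A single-month series gets G = 0.
    """
    g = np.zeros_like(t_mean, dtype=float)
    if t_mean.size >= 2:
        g[0] = 0.14 * (t_mean[1] - t_mean[0])
        g[-1] = 0.14 * (t_mean[-1] - t_mean[-2])
    if t_mean.size >= 3:
        g[1:-1] = 0.07 * (t_mean[2:] - t_mean[:-2])
    return g


def validate_station_table(df: pd.DataFrame) -> None:
    """Check schema and physical invariants of a station monthly table."""
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"station table missing required field(s): {', '.join(missing)}")
    dup = df.duplicated(subset=["station_id", "year", "month"])
    if dup.any():
        rows = df.loc[dup, ["station_id", "year", "month"]].head(5).to_dict("records")
        raise DataError(f"duplicate station-months: {rows}")
    if not df["month"].between(1, 12).all():
        raise DataError("month outside 1..12")
    with_t = df.dropna(subset=["t_min", "t_mean", "t_max"])
    if ((with_t["t_min"] > with_t["t_mean"]) | (with_t["t_mean"] > with_t["t_max"])).any():
        raise DataError("temperature ordering t_min <= t_mean <= t_max violated")
    if (df["precip"].dropna() < 0).any():
        raise DataError("negative precipitation")
    rh = df["rel_humidity"].dropna()
    if ((rh < 0) | (rh > 100)).any():
        raise DataError("relative humidity outside [0, 100] %")
    if (df["sunshine_hours"].dropna() < 0).any():
        raise DataError("negative sunshine hours")


def station_et0_series(
    records: pd.DataFrame,
    floor: bool = True,
    angstrom_as: float = ANGSTROM_AS,
    angstrom_bs: float = ANGSTROM_BS,
    albedo: float = ALBEDO,
) -> pd.DataFrame:
    """Monthly ET0 for every station-month in ``records``.

    ``records`` is a station monthly table (see ``STATION_COLUMNS``).
    Station-months missing any field required for ET0 are dropped and the
    count is logged; missing pressure is derived from elevation and missing
    anemometer height defaults to 10 m (both logged). Returns a frame with
    columns station_id, year, month, et0_daily, et0_month sorted by
    (station_id, year, month).
    """
    validate_station_table(records)
    df = records.sort_values(["station_id", "year", "month"]).reset_index(drop=True)
    n_in = len(df)
    df = df.dropna(subset=list(_ET0_REQUIRED)).reset_index(drop=True)
    if len(df) < n_in:
        log.warning("dropped %d station-month(s) with missing required fields", n_in - len(df))
    if df.empty:
        return pd.DataFrame(columns=["station_id", "year", "month", "et0_daily", "et0_month"])

    n_no_height = df["anemometer_height"].isna().sum()
    if n_no_height:
        log.info("assumed %.0f m anemometer height for %d record(s)", DEFAULT_ANEMOMETER_HEIGHT, n_no_height)
    height = df["anemometer_height"].fillna(DEFAULT_ANEMOMETER_HEIGHT).to_numpy(float)
    n_no_p = df["pressure"].isna().sum()
    if n_no_p:
        log.info("derived pressure from elevation for %d record(s)", n_no_p)
    pressure = df["pressure"].to_numpy(float)
    pressure = np.where(
        np.isnan(pressure), pressure_from_elevation(df["elevation"].to_numpy(float)), pressure
    )

    e_s, e_a = vapor_pressure_terms(
        df["t_max"].to_numpy(float), df["t_min"].to_numpy(float), df["rel_humidity"].to_numpy(float)
    )
    delta = slope_delta(df["t_mean"].to_numpy(float))
    gamma = psychrometric_gamma(pressure)
    u2 = wind_at_2m(df["wind_speed"].to_numpy(float), height)
    r_n = net_radiation(
        df["lat"].to_numpy(float),
        df["month"].to_numpy(int),
        df["t_max"].to_numpy(float),
        df["t_min"].to_numpy(float),
        e_a,
        np.minimum(
            df["sunshine_hours"].to_numpy(float),
            daylight_hours(df["lat"].to_numpy(float), df["month"].to_numpy(int)),
        ),
        angstrom_as=angstrom_as,
        angstrom_bs=angstrom_bs,
        albedo=albedo,
    )
    g = (
        df.groupby("station_id", sort=False)["t_mean"]
        .transform(lambda s: pd.Series(_soil_heat_flux_series(s.to_numpy(float)), index=s.index))
        .to_numpy(float)
    )

    rate = _pm_rate(delta, r_n, g, gamma, df["t_mean"].to_numpy(float), u2, e_s, e_a)
    if floor:
        n_floored = int((rate < 0).sum())
        if n_floored:
            log.info("floored %d negative ET0 month(s) at zero", n_floored)
        rate = np.maximum(rate, 0.0)

    ndays = np.array([days_in_month(y, m) for y, m in zip(df["year"], df["month"])], dtype=float)
    out = pd.DataFrame(
        {
            "station_id": df["station_id"],
            "year": df["year"].astype(int),
            "month": df["month"].astype(int),
            "et0_daily": rate,
            "et0_month": rate * ndays,
        }
    )
    return out


def annual_et0(et0_table: pd.DataFrame) -> pd.DataFrame:
    """Sum monthly ET0 to station-year totals (mm/year)."""
    return (
        et0_table.groupby(["station_id", "year"], as_index=False)["et0_month"]
        .sum()
        .rename(columns={"et0_month": "et0_annual"})
    )
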