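"""Seasonal crop-coefficient (Kc) curves with climate adjustment.

The single crop coefficient method divides a crop season into four stages
(initial, development, mid-season, late season). FAO tabulated standard
values supply Kc_ini, Kc_mid and Kc_end; the mid and end values are
adjusted for local wind speed, minimum relative humidity and crop height:

    Kc = Kc_std + [0.04 (u2 − 2) − 0.004 (RHmin − 45)] (h/3)^0.3

with RHmin estimated from monthly temperature extremes as
e°(Tmin)/e°(Tmax) × 100%. The daily curve is constant at Kc_ini over the
initial stage, ramps linearly to the adjusted Kc_mid across development,
holds it through mid-season, and ramps linearly to the adjusted Kc_end
across the late stage.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .meteo_et0 import saturation_vapor_pressure

log = logging.getLogger(__name__)

#: Allowed range for any (adjusted) crop coefficient; values outside are
#: clipped with a logged warning.
KC_BOUNDS = (0.1, 1.5)

CROPS = ("wheat", "corn", "cotton")

#: FAO-style standard coefficients and typical crop heights (m).
DEFAULT_KC_PARAMS: Mapping[str, Mapping[str, float]] = {
    "wheat": {"kc_ini": 0.30, "kc_mid": 1.15, "kc_end": 0.25, "height_m": 1.0},
    "corn": {"kc_ini": 0.30, "kc_mid": 1.20, "kc_end": 0.35, "height_m": 2.0},
    "cotton": {"kc_ini": 0.35, "kc_mid": 1.15, "kc_end": 0.70, "height_m": 1.3},
}

#: Default single-season calendars for an arid temperate planting zone:
#: spring wheat early April through mid-August, corn late April through
#: mid-September, cotton early April through late October.
DEFAULT_CALENDARS: Mapping[str, Mapping[str, object]] = {
    "wheat": {"start_day": 91, "stage_lengths": (20, 25, 60, 30)},
    "corn": {"start_day": 110, "stage_lengths": (30, 40, 50, 30)},
    "cotton": {"start_day": 100, "stage_lengths": (30, 50, 60, 55)},
}


@dataclass(frozen=True)
class CropCalendar:
    """Season timing: planting day-of-year and the four stage lengths (days)."""

    crop: str
    start_day: int
    stage_lengths: tuple[int, int, int, int]
    region_id: str | None = None

    def __post_init__(self):
        if len(self.stage_lengths) != 4 or any(int(d) <= 0 for d in self.stage_lengths):
            raise InputError("all four stage lengths must be positive")
        if self.start_day < 1:
            raise InputError("start_day must be a day-of-year >= 1")
        if self.start_day + self.total_days - 1 > 366:
            raise InputError("season must fit within one calendar year")

    @property
    def total_days(self) -> int:
        return int(sum(self.stage_lengths))


@dataclass(frozen=True)
class KcProfile:
    """Standard and (optionally) climate-adjusted stage coefficients."""

    crop: str
    kc_ini: float
    kc_mid_std: float
    kc_end_std: float
    crop_height_h: float
    kc_mid_adj: float | None = None
    kc_end_adj: float | None = None

    @property
    def kc_mid(self) -> float:
        return self.kc_mid_std if self.kc_mid_adj is None else self.kc_mid_adj

    @property
    def kc_end(self) -> float:
        return self.kc_end_std if self.kc_end_adj is None else self.kc_end_adj


@dataclass(frozen=True)
class KcAdjustClimate:
    """Stage-mean climate entering the Kc_mid / Kc_end adjustment."""

    u2_mid: float
    rh_min_mid: float
    u2_end: float
    rh_min_end: float


def load_crop_params(path) -> dict:
    """Read per-crop Kc standard values, heights and calendars from YAML.

    Schema: ``{crop: {kc_ini, kc_mid, kc_end, height_m, start_day,
    stage_lengths: [4 ints]}}``; any crop or key omitted falls back to the
    shipped defaults.
    """
    import yaml

    raw = yaml.safe_load(open(path)) or {}
    kc_params = {}
    calendars = {}
    for crop, entry in raw.items():
        base_kc = dict(DEFAULT_KC_PARAMS.get(crop, {}))
        base_cal = dict(DEFAULT_CALENDARS.get(crop, {}))
        for key in ("kc_ini", "kc_mid", "kc_end", "height_m"):
            if key in entry:
                base_kc[key] = float(entry[key])
        for key in ("start_day", "stage_lengths"):
            if key in entry:
                base_cal[key] = entry[key]
        kc_params[crop] = base_kc
        calendars[crop] = base_cal
    return {"kc_params": kc_params, "calendars": calendars}


def default_profile(crop: str, params: Mapping | None = None) -> KcProfile:
    params = (params or DEFAULT_KC_PARAMS)[crop]
    return KcProfile(
        crop=crop,
        kc_ini=params["kc_ini"],
        kc_mid_std=params["kc_mid"],
        kc_end_std=params["kc_end"],
        crop_height_h=params["height_m"],
    )


def default_calendar(crop: str, params: Mapping | None = None) -> CropCalendar:
    params = (params or DEFAULT_CALENDARS)[crop]
    return CropCalendar(
        crop=crop,
        start_day=int(params["start_day"]),
        stage_lengths=tuple(int(d) for d in params["stage_lengths"]),
    )


def rh_min_from_temps(t_min, t_max):
    """Minimum relative humidity (%) from monthly temperature extremes.

    RHmin = e°(Tmin) / e°(Tmax) × 100, the FAO estimate when dew-point or
    humidity extremes are not observed.
    """
    t_min_arr = np.asarray(t_min, dtype=float)
    t_max_arr = np.asarray(t_max, dtype=float)
    if np.any(t_min_arr > t_max_arr):
        raise InputError("t_min must not exceed t_max")
    out = saturation_vapor_pressure(t_min) / saturation_vapor_pressure(t_max) * 100.0
    return out


def _kc_climate_term(u2, rh_min, h):
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr <= 0):
        raise InputError("crop height h must be positive")
    rh_arr = np.asarray(rh_min, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise InputError("rh_min must lie in [0, 100] %")
    u2 = np.asarray(u2, dtype=float)
    return (0.04 * (u2 - 2.0) - 0.004 * (rh_arr - 45.0)) * (h_arr / 3.0) ** 0.3


def clip_kc(value):
    """Clip a coefficient to ``KC_BOUNDS`` with a logged warning."""
    lo, hi = KC_BOUNDS
    arr = np.asarray(value, dtype=float)
    n_out = int(((arr < lo) | (arr > hi)).sum())
    if n_out:
        log.warning("clipped %d crop coefficient(s) to [%.2f, %.2f]", n_out, lo, hi)
    clipped = np.clip(arr, lo, hi)
    return float(clipped) if np.ndim(value) == 0 else clipped


def adjust_kc_mid(kc_mid_std, u2, rh_min, h, clip: bool = True):
    """Climate-adjusted mid-season coefficient.

    Unchanged at the reference climate (u2 = 2 m/s, RHmin = 45%); increases
    with wind, decreases with humidity, scaled by (h/3)^0.3.
    """
    out = np.asarray(kc_mid_std, dtype=float) + _kc_climate_term(u2, rh_min, h)
    out = float(out) if np.ndim(out) == 0 else out
    return clip_kc(out) if clip else out


def adjust_kc_end(kc_end_std, u2, rh_min, h, clip: bool = True):
    """Climate-adjusted end-season coefficient (same correction as mid)."""
    out = np.asarray(kc_end_std, dtype=float) + _kc_climate_term(u2, rh_min, h)
    out = float(out) if np.ndim(out) == 0 else out
    return clip_kc(out) if clip else out


def adjusted_profile(profile: KcProfile, climate: KcAdjustClimate, clip: bool = True) -> KcProfile:
    """Fill ``kc_mid_adj`` / ``kc_end_adj`` from stage-mean climate."""
    return replace(
        profile,
        kc_mid_adj=float(
            adjust_kc_mid(profile.kc_mid_std, climate.u2_mid, climate.rh_min_mid, profile.crop_height_h, clip=clip)
        ),
        kc_end_adj=float(
            adjust_kc_end(profile.kc_end_std, climate.u2_end, climate.rh_min_end, profile.crop_height_h, clip=clip)
        ),
    )


@dataclass(frozen=True)
class KcCurve:
    """Daily Kc over one season; ``values[i]`` is day ``start_day + i`` of the year."""

    crop: str
    start_day: int
    values: np.ndarray

    @property
    def end_day(self) -> int:
        return self.start_day + len(self.values) - 1


def build_kc_curve(calendar_: CropCalendar, profile: KcProfile) -> KcCurve:
    """Piecewise-linear four-stage daily Kc series.

    Ramps reach their target on the stage's last day, so the final season
    day equals the adjusted Kc_end exactly and the day halfway through
    development equals the midpoint of Kc_ini and Kc_mid.
    """
    l1, l2, l3, l4 = (int(d) for d in calendar_.stage_lengths)
    kc_ini, kc_mid, kc_end = profile.kc_ini, profile.kc_mid, profile.kc_end
    values = np.empty(calendar_.total_days, dtype=float)
    values[:l1] = kc_ini
    frac_dev = (np.arange(1, l2 + 1)) / l2
    values[l1 : l1 + l2] = kc_ini + frac_dev * (kc_mid - kc_ini)
    values[l1 + l2 : l1 + l2 + l3] = kc_mid
    frac_late = (np.arange(1, l4 + 1)) / l4
    values[l1 + l2 + l3 :] = kc_mid + frac_late * (kc_end - kc_mid)
    return KcCurve(crop=calendar_.crop, start_day=calendar_.start_day, values=values)


def monthly_kc(curve: KcCurve, year: int) -> pd.Series:
    """Per-month mean Kc for ``year``; zero outside the season.

    The mean for a month counts out-of-season days as zero, so a month half
    covered by a constant-1 season averages 0.5.
    """
    n_year = 366 if calendar.isleap(int(year)) else 365
    if curve.end_day > n_year:
        raise InputError(f"season extends past day {n_year} of {year}")
    daily = np.zeros(n_year)
    daily[curve.start_day - 1 : curve.end_day] = curve.values
    month_of_day = np.concatenate(
        [np.full(calendar.monthrange(int(year), m)[1], m) for m in range(1, 13)]
    )
    means = pd.Series(daily).groupby(month_of_day).mean()
    means.index.name = "month"
    means.name = "kc"
    return means


def seasonal_kc_total(curve: KcCurve) -> float:
    """Day-weighted integral of the seasonal curve (sum of daily Kc)."""
    return float(curve.values.sum())


_STAGES = ("initial", "development", "mid", "late")
_CUM_MONTH_DAYS = np.cumsum([calendar.monthrange(2001, m)[1] for m in range(1, 13)])


def _month_of_doy(doy: int) -> int:
    return int(np.searchsorted(_CUM_MONTH_DAYS, doy) + 1)


def stage_months(calendar_: CropCalendar) -> dict[str, tuple[int, ...]]:
    """Calendar months overlapped by each growth stage (non-leap basis).

    Used to pick which months of a climate series feed the stage-mean wind
    and humidity in the Kc_mid / Kc_end adjustments.
    """
    out = {}
    start = calendar_.start_day
    for stage, length in zip(_STAGES, calendar_.stage_lengths):
        end = start + int(length) - 1
        out[stage] = tuple(range(_month_of_doy(start), _month_of_doy(min(end, 365)) + 1))
        start = end + 1
    return out
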