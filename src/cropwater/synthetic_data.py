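"""Seeded synthetic inputs emulating an arid irrigated province.

The default ("xinjiang_like") scenario mirrors the study conditions of a
large endorheic province: 66 monthly meteorological stations over
1995–2017 spread across 15 prefecture-level regions in four basins, three
climate archetypes (hot dry ``arid_basin``, wetter cooler
``mountain_margin``, ``intermediate``), per-basin warming rates, a strong
expansion of total crop area (1.95e4 → 4.53e4 km², factor 2.32) with the
crop mix drifting toward cotton, published per-region irrigation
efficiencies, and actual withdrawals constructed from the demand table
with a known per-region bias so balance recovery is testable.

Randomness is split into one stream per table (stations / meteorology /
areas / actuals), all derived from the scenario seed, so regenerating one
table never shifts another.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError
from .meteo_et0 import STATION_COLUMNS, daylight_hours, pressure_from_elevation

#: Stream index per table, combined with the scenario seed.
_STREAMS = {"stations": 0, "meteo": 1, "areas": 2, "actuals": 3}

#: Climate archetypes: annual-mean temperature (°C at the 600 m reference
#: elevation), seasonal amplitude, annual precipitation (mm), mean relative
#: humidity (%), mean 10 m wind (m/s), base sunshine (h/day), diurnal
#: temperature range (°C) and the station elevation range (m).
ARCHETYPES: Mapping[str, Mapping[str, float | tuple]] = {
    "arid_basin": dict(
        t_annual=11.0, t_amp=16.0, precip_annual=42.0, rh_base=45.0,
        wind_mean=2.3, sun_base=8.8, diurnal=13.0, elev_range=(300.0, 1100.0),
    ),
    "intermediate": dict(
        t_annual=7.5, t_amp=17.0, precip_annual=180.0, rh_base=55.0,
        wind_mean=2.0, sun_base=8.0, diurnal=11.0, elev_range=(400.0, 1000.0),
    ),
    "mountain_margin": dict(
        t_annual=8.5, t_amp=14.0, precip_annual=340.0, rh_base=65.0,
        wind_mean=1.6, sun_base=6.8, diurnal=10.0, elev_range=(700.0, 1500.0),
    ),
}

_BASIN_ARCHETYPE = {
    "Tarim": "arid_basin",
    "Turpan-Hami": "arid_basin",
    "Junggar": "intermediate",
    "Yili": "mountain_margin",
}

#: Basin warming rates, °C/decade.
DEFAULT_WARMING = {"Junggar": 0.27, "Tarim": 0.35, "Turpan-Hami": 0.54, "Yili": 0.52}

#: (region, basin, share of total crop area, lon, lat) for the 15 prefectures.
_REGION_TABLE = (
    ("Kashgar", "Tarim", 0.210, 76.0, 39.5),
    ("Aksu", "Tarim", 0.180, 80.3, 41.2),
    ("Bazhou", "Tarim", 0.090, 86.1, 41.8),
    ("Hotan", "Tarim", 0.050, 79.9, 37.3),
    ("Kezhou", "Tarim", 0.020, 76.2, 39.7),
    ("Changji", "Junggar", 0.100, 87.3, 44.0),
    ("Tacheng", "Junggar", 0.090, 83.0, 46.6),
    ("Shihezi", "Junggar", 0.050, 86.0, 44.3),
    ("Bozhou", "Junggar", 0.040, 82.1, 44.9),
    ("Aletai", "Junggar", 0.030, 88.1, 47.6),
    ("Urumqi", "Junggar", 0.005, 87.6, 43.8),
    ("Karamay", "Junggar", 0.005, 84.9, 45.6),
    ("Yili", "Yili", 0.090, 81.3, 43.9),
    ("Turpan", "Turpan-Hami", 0.020, 89.2, 42.9),
    ("Hami", "Turpan-Hami", 0.025, 93.5, 42.8),
)

#: Published per-prefecture irrigation efficiencies.
DEFAULT_EFFICIENCY = {
    "Aksu": 0.70, "Aletai": 0.62, "Bazhou": 0.65, "Bozhou": 0.60,
    "Changji": 0.70, "Hami": 0.66, "Hotan": 0.72, "Kashgar": 0.63,
    "Kezhou": 0.60, "Karamay": 0.79, "Shihezi": 0.71, "Tacheng": 0.69,
    "Turpan": 0.79, "Urumqi": 0.78, "Yili": 0.73,
}

#: Crop-mix endpoints (fractions of regional crop area), derived from the
#: printed 1995 / 2017 per-crop areas; normalized before use.
CROP_SHARES_START = {"cotton": 0.349, "wheat": 0.452, "corn": 0.192}
CROP_SHARES_END = {"cotton": 0.521, "wheat": 0.250, "corn": 0.224}

_M_PER_DEG_LAT = 110_540.0
_M_PER_DEG_LON = 111_320.0 * np.cos(np.deg2rad(42.0))


def _planar(lon, lat):
    return np.asarray(lon) * _M_PER_DEG_LON, np.asarray(lat) * _M_PER_DEG_LAT


@dataclass(frozen=True)
class RegionSpec:
    region_id: str
    basin_id: str
    archetype: str
    area_weight: float
    lon: float
    lat: float
    ie: float


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete parameterization of one synthetic study."""

    seed: int
    n_stations: int = 66
    years: tuple[int, int] = (1995, 2017)
    regions: tuple[RegionSpec, ...] = ()
    total_area_start_km2: float = 1.95e4
    total_area_end_km2: float = 4.53e4
    crop_shares_start: Mapping[str, float] = field(default_factory=lambda: dict(CROP_SHARES_START))
    crop_shares_end: Mapping[str, float] = field(default_factory=lambda: dict(CROP_SHARES_END))
    warming_c_per_decade: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WARMING))
    precip_trend_mm_per_decade: float = 0.0
    actuals_bias: float | Mapping[str, float] | None = -0.34
    actuals_noise_sd_m3: float = 0.0

    def __post_init__(self):
        if self.n_stations < 1:
            raise InputError("n_stations must be >= 1")
        if self.years[1] < self.years[0]:
            raise InputError("years must be an inclusive (start, end) range")
        if not self.regions:
            object.__setattr__(self, "regions", _default_regions())

    @classmethod
    def xinjiang_like(cls, seed: int = 0, **overrides) -> "SyntheticScenario":
        return cls(seed=seed, **overrides)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def basins(self) -> dict[str, str]:
        return {r.region_id: r.basin_id for r in self.regions}

    def rng(self, table: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[table]])


def _default_regions() -> tuple[RegionSpec, ...]:
    return tuple(
        RegionSpec(
            region_id=rid,
            basin_id=basin,
            archetype=_BASIN_ARCHETYPE[basin],
            area_weight=w,
            lon=lon,
            lat=lat,
            ie=DEFAULT_EFFICIENCY[rid],
        )
        for rid, basin, w, lon, lat in _REGION_TABLE
    )


def efficiency_table(scenario: SyntheticScenario) -> pd.DataFrame:
    return pd.DataFrame(
        {"region_id": [r.region_id for r in scenario.regions], "ie": [r.ie for r in scenario.regions]}
    )


def _station_counts(scenario: SyntheticScenario) -> list[int]:
    """Largest-remainder allocation of stations to regions (>= 1 each)."""
    weights = np.array([r.area_weight for r in scenario.regions], dtype=float)
    n_regions = len(weights)
    if scenario.n_stations < n_regions:
        # fewer stations than regions: give one to the heaviest regions
        counts = np.zeros(n_regions, dtype=int)
        order = np.argsort(-weights, kind="stable")
        counts[order[: scenario.n_stations]] = 1
        return counts.tolist()
    remaining = scenario.n_stations - n_regions
    quota = weights / weights.sum() * remaining
    counts = np.floor(quota).astype(int)
    leftover = remaining - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    counts[order[:leftover]] += 1
    return (counts + 1).tolist()


def gen_stations(scenario: SyntheticScenario) -> pd.DataFrame:
    """Station table: id, region, basin, archetype, lon/lat, planar x/y, elevation."""
    rng = scenario.rng("stations")
    counts = _station_counts(scenario)
    rows = []
    k = 0
    for region, n in zip(scenario.regions, counts):
        arch = ARCHETYPES[region.archetype]
        lo, hi = arch["elev_range"]
        for _ in range(n):
            k += 1
            lon = region.lon + rng.uniform(-0.8, 0.8)
            lat = region.lat + rng.uniform(-0.5, 0.5)
            rows.append(
                {
                    "station_id": f"S{k:02d}",
                    "region_id": region.region_id,
                    "basin_id": region.basin_id,
                    "archetype": region.archetype,
                    "lon": lon,
                    "lat": lat,
                    "elevation": rng.uniform(lo, hi),
                }
            )
    df = pd.DataFrame(rows)
    df["x"], df["y"] = _planar(df["lon"].to_numpy(), df["lat"].to_numpy())
    return df


def gen_region_geometries(scenario: SyntheticScenario):
    """Representative cropland cells per region: centre plus four offsets."""
    from .spatial_regions import RegionGeometry

    offsets = ((0.0, 0.0, 0.40), (0.3, 0.0, 0.15), (-0.3, 0.0, 0.15), (0.0, 0.2, 0.15), (0.0, -0.2, 0.15))
    geoms = []
    for region in scenario.regions:
        cells = []
        for dlon, dlat, w in offsets:
            x, y = _planar(region.lon + dlon, region.lat + dlat)
            cells.append((float(x), float(y), w))
        geoms.append(RegionGeometry(region_id=region.region_id, basin_id=region.basin_id, cells=tuple(cells)))
    return geoms


def gen_monthly_meteo(scenario: SyntheticScenario, stations: pd.DataFrame) -> pd.DataFrame:
    """Monthly station meteorology with archetype climate and basin warming.

    Temperature is a seasonal sinusoid around the archetype mean (lapsed
    4 °C/km from 600 m) plus the basin warming trend and Gaussian noise;
    precipitation uses per-month gamma draws whose expectations sum to the
    archetype annual total; humidity is anti-correlated with the seasonal
    temperature anomaly; sunshine is bounded by daylight hours.
    """
    rng = scenario.rng("meteo")
    years = np.array(scenario.year_list)
    months = np.arange(1, 13)
    n_st, n_y, n_m = len(stations), len(years), 12

    sid = np.repeat(stations["station_id"].to_numpy(), n_y * n_m)
    lat = np.repeat(stations["lat"].to_numpy(float), n_y * n_m)
    lon = np.repeat(stations["lon"].to_numpy(float), n_y * n_m)
    elev = np.repeat(stations["elevation"].to_numpy(float), n_y * n_m)
    arch_names = np.repeat(stations["archetype"].to_numpy(), n_y * n_m)
    basin = np.repeat(stations["basin_id"].to_numpy(), n_y * n_m)
    year = np.tile(np.repeat(years, n_m), n_st)
    month = np.tile(months, n_st * n_y)

    def arch_param(key):
        lut = {name: float(p[key]) for name, p in ARCHETYPES.items()}
        return np.vectorize(lut.get)(arch_names).astype(float)

    t_annual = arch_param("t_annual") - 4.0 * (elev - 600.0) / 1000.0
    t_amp = arch_param("t_amp")
    seasonal = -np.cos(2.0 * np.pi * (month - 1) / 12.0)
    warming = np.vectorize(scenario.warming_c_per_decade.get)(basin).astype(float)
    years_elapsed = (year - scenario.years[0]) + (month - 0.5) / 12.0
    t_mean = t_annual + t_amp * seasonal + warming / 10.0 * years_elapsed + rng.normal(0.0, 0.8, sid.size)

    diurnal = arch_param("diurnal") * (1.0 + 0.1 * seasonal)
    up_frac = rng.uniform(0.45, 0.55, sid.size)
    t_max = t_mean + diurnal * up_frac
    t_min = t_max - diurnal

    precip_annual = arch_param("precip_annual") + scenario.precip_trend_mm_per_decade / 10.0 * (
        year - scenario.years[0]
    )
    month_weight = (1.0 + 0.6 * seasonal) / 12.0
    precip_mean = np.maximum(precip_annual * month_weight, 0.05)
    precip = rng.gamma(shape=2.0, scale=precip_mean / 2.0)

    rh = np.clip(
        arch_param("rh_base") - 0.6 * (t_amp * seasonal) + rng.normal(0.0, 4.0, sid.size), 10.0, 95.0
    )
    wind = np.clip(rng.normal(arch_param("wind_mean"), 0.5, sid.size), 0.3, 6.0)
    sun = np.clip(arch_param("sun_base") + 1.8 * seasonal + rng.normal(0.0, 0.6, sid.size), 2.0, None)
    sun = np.minimum(sun, daylight_hours(lat, month) * 0.98)

    df = pd.DataFrame(
        {
            "station_id": sid,
            "lat": lat,
            "lon": lon,
            "elevation": elev,
            "year": year,
            "month": month,
            "t_max": t_max,
            "t_min": t_min,
            "t_mean": t_mean,
            "precip": precip,
            "wind_speed": wind,
            "anemometer_height": 10.0,
            "pressure": pressure_from_elevation(elev),
            "rel_humidity": rh,
            "sunshine_hours": sun,
        }
    )
    return df[list(STATION_COLUMNS)]


def gen_crop_areas(scenario: SyntheticScenario) -> pd.DataFrame:
    """Region-year-crop planting areas (km²).

    Regional totals interpolate linearly between the start and end
    province totals (split by region weight, with one fixed multiplicative
    wobble per region); crop shares interpolate between the normalized
    start and end mixes, so shares sum to one every region-year and the
    cotton share is monotone when its drift is positive.
    """
    rng = scenario.rng("areas")
    crops = sorted(scenario.crop_shares_start)
    s0 = np.array([scenario.crop_shares_start[c] for c in crops], dtype=float)
    s1 = np.array([scenario.crop_shares_end[c] for c in crops], dtype=float)
    s0, s1 = s0 / s0.sum(), s1 / s1.sum()
    y0, y1 = scenario.years
    span = max(y1 - y0, 1)
    wobble = {r.region_id: float(np.exp(rng.normal(0.0, 0.03))) for r in scenario.regions}
    rows = []
    for region in scenario.regions:
        for year in scenario.year_list:
            frac = (year - y0) / span
            total = (
                scenario.total_area_start_km2
                + (scenario.total_area_end_km2 - scenario.total_area_start_km2) * frac
            )
            region_total = region.area_weight * total * wobble[region.region_id]
            shares = s0 + (s1 - s0) * frac
            for crop, share in zip(crops, shares):
                rows.append(
                    {
                        "region_id": region.region_id,
                        "year": year,
                        "crop": crop,
                        "area_km2": region_total * share,
                    }
                )
    return pd.DataFrame(rows)


def gen_actuals(
    scenario: SyntheticScenario,
    demand_table: pd.DataFrame,
    bias: float | Mapping[str, float] | None = None,
    noise_sd_m3: float | None = None,
) -> pd.DataFrame:
    """Actual irrigation per region-year: ia = iwr·(1 + bias) + noise.

    ``bias`` may be a scalar, a per-region mapping, or None to use the
    scenario default (drawn per region from U(−0.5, 0.15) when the scenario
    default is None). The applied per-region bias is stored in
    ``result.attrs['bias']``; with zero bias and zero noise every ΔW is 0.
    """
    rng = scenario.rng("actuals")
    if bias is None:
        bias = scenario.actuals_bias
    if noise_sd_m3 is None:
        noise_sd_m3 = scenario.actuals_noise_sd_m3
    iwr = demand_table.groupby(["region_id", "year"], as_index=False)["iwr_m3"].sum()
    regions = sorted(set(iwr["region_id"]))
    if bias is None:
        bias_map = {r: float(rng.uniform(-0.5, 0.15)) for r in regions}
    elif isinstance(bias, Mapping):
        missing = [r for r in regions if r not in bias]
        if missing:
            raise InputError(f"bias mapping missing region(s): {', '.join(missing)}")
        bias_map = {r: float(bias[r]) for r in regions}
    else:
        bias_map = {r: float(bias) for r in regions}
    b = iwr["region_id"].map(bias_map).to_numpy(float)
    noise = rng.normal(0.0, 1.0, len(iwr)) * float(noise_sd_m3)
    ia = np.maximum(iwr["iwr_m3"].to_numpy(float) * (1.0 + b) + noise, 0.0)
    out = pd.DataFrame({"region_id": iwr["region_id"], "year": iwr["year"], "ia_m3": ia})
    out.attrs["bias"] = bias_map
    return out


def generate_all(scenario: SyntheticScenario) -> dict:
    """All pipeline inputs for a scenario (stations, meteo, geometry, areas, efficiency)."""
    stations = gen_stations(scenario)
    return {
        "stations": stations,
        "meteo": gen_monthly_meteo(scenario, stations),
        "regions": gen_region_geometries(scenario),
        "areas": gen_crop_areas(scenario),
        "efficiency": efficiency_table(scenario),
        "basins": scenario.basins,
    }
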