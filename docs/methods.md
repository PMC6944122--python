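# Methods

## Scope and cadence

`cropwater` estimates crop irrigation water requirements (IWR) and the
regional water balance for an arid, irrigation-dominated province at
monthly, prefecture-level resolution, and attributes IWR variation to
planting area versus temperature. All computation is monthly: the input
meteorology is monthly means, reference evapotranspiration (ET₀) is a
daily rate from those means multiplied by the calendar length of the month
(29 days in leap-year February), and the water balance is annual because
actual withdrawals are reported annually.

## Reference evapotranspiration

ET₀ uses the Penman-Monteith combination equation on a reference grass
surface. The sub-terms follow the standard FAO-56 forms: saturation vapor
pressure e°(T) = 0.6108·exp(17.27T/(T+237.3)); Δ = 4098·e°(T)/(T+237.3)²;
γ = 0.665×10⁻³·P with P = 101.3·((293−0.0065z)/293)^5.26 when station
pressure is missing; wind converted to 2 m by the log profile
u₂ = u_z·4.87/ln(67.8z−5.42); extraterrestrial radiation Ra from latitude
and the representative day (the 15th of each month); shortwave
Rs = (a_s + b_s·n/N)·Ra with Angström coefficients a_s = 0.25, b_s = 0.50;
net shortwave with albedo 0.23; net longwave by Stefan-Boltzmann
(4.903×10⁻⁹) on the mean of Tmax⁴ and Tmin⁴ with the vapor-pressure and
cloudiness factors, clear sky at 0.75·Ra. Every constant is a
configuration override.

Numerical choices:

- **Soil heat flux.** Interior months use the centered monthly form
  G = 0.07(T₊₁ − T₋₁). The one-sided form 0.14(Tᵢ − Tᵢ₋₁) applies at the
  final month of a station series; the first month, which has no
  predecessor, uses the mirrored form 0.14(Tᵢ₊₁ − Tᵢ). A single-month
  series takes G = 0.
- **Flooring.** Negative ET₀ rates (possible when Rn < G with no vapor
  deficit) are floored at zero and counted in the log. No aridity
  correction or negative-longwave capping is applied.
- **Missing data.** A station-month lacking any field required for ET₀ is
  dropped and reported; missing pressure is derived from elevation and a
  missing anemometer height defaults to the 10 m met-screen standard, both
  logged. No imputation is performed.
- The sunshine fraction n/N is clipped to [0, 1]; polar latitudes
  (|φ| ≥ 66.5°) are rejected as unsupported rather than approximated.

## Crop coefficients

The single-coefficient method splits each crop season into initial,
development, mid and late stages. Shipped standards (all overridable per
region through a YAML config): spring wheat 0.30/1.15/0.25 at h = 1.0 m,
Apr–mid-Aug (stages 20/25/60/30 d); corn 0.30/1.20/0.35 at h = 2.0 m,
late Apr–mid-Sep (30/40/50/30 d); cotton 0.35/1.15/0.70 at h = 1.3 m,
Apr–late Oct (30/50/60/55 d). Seasons are single-cropped and must fit in
one calendar year.

Kc_mid and Kc_end are adjusted per region-year with the wind/humidity
correction [0.04(u₂−2) − 0.004(RHmin−45)](h/3)^0.3, where u₂ and RHmin are
means over the months overlapped by the mid (respectively late) stage of
that region's climate series, and RHmin is estimated from monthly
temperature extremes as e°(Tmin)/e°(Tmax)·100. Adjusted coefficients are
clipped to [0.1, 1.5] with a logged warning.

The daily curve is constant at Kc_ini, ramps linearly across development,
holds Kc_mid, and ramps to Kc_end. Ramps reach their target on the stage's
final day, so the last season day equals Kc_end exactly and the halfway
day of development equals the midpoint value. Monthly Kc is the mean over
calendar days counting out-of-season days as zero.

## Demand and units

Effective precipitation is a single empirical scalar, Pe = 0.52·P, applied
to all regions and months. CWR = ETc − Pe is clamped at zero by default —
negative irrigation is physically meaningless for scheduling — with a flag
to keep the raw difference (the withdrawal volume is still floored at
zero, since a wet month cannot produce negative gross withdrawal).
IWR = A·CWR/Ie converts with 1 mm over 1 km² = 1000 m³; areas are annual
(yearbook granularity) and applied to every month of the year, with the
in-season Kc deciding which months actually draw water. Regions with
planted area but no efficiency or basin entry fail loudly rather than
defaulting. Aggregation sums through canonical per-region subtotals in
sorted order so basin totals are bit-identical to the sum of their
prefectures — the additivity audit is exact, not approximate.

## Regionalization

Thiessen polygons are implemented as nearest-station assignment of
discrete representative cropland cells, mathematically equivalent on a
raster and exactly testable against a brute-force scan. Distance is
Euclidean on projected planar metres (a great-circle option exists for
lon/lat inputs); exact distance ties break to the lexicographically
smallest station id. The regional series is the cropland-weighted mean of
the assigned stations' series, and a station missing any month raises an
error naming station and month.

## Balance, trends, attribution

The soil-water balance neglects surface runoff, deep drainage and the
water-table contribution (flat irrigated land, deep groundwater,
low-intensity rain); they remain explicit zero-valued fields so the full
balance can be exercised and extended. ΔW = Ia − IWR per region-year;
|ΔW| < 0.01×10⁹ m³ counts as balanced, and ΔW ≤ −1×10⁹ m³ is flagged as
serious scarcity (both configurable). Trends are ordinary least squares on
calendar year via `scipy.stats.linregress`, reported per year and per
decade, requiring ≥ 3 distinct years.

Attribution fits a random-forest regression of annual IWR on planting
area and growing-season (Apr–Oct) mean temperature per crop, with an
80/20 train/holdout split. Importance is permutation-based on the holdout
— estimator-agnostic and testable by construction — max-normalized to a
0–100 scale. Because the study's absolute skill metrics depend on
proprietary yearbook data, only the ordinal claim (area outranks
temperature) is treated as a reproducible result.

## Synthetic scenario

The default scenario fixes the study conditions: 66 stations across 15
prefectures in four basins over 1995–2017. Three climate archetypes set
annual-mean temperature (11.0/7.5/8.5 °C at a 600 m reference, lapsed at
4 °C/km), seasonal amplitude (16/17/14 °C), annual precipitation
(42/180/340 mm — the dry-basin value is the driest basin's reported mean,
the wet value the mountain-margin basin's), humidity, wind, sunshine and
elevation ranges. Basin warming rates are 0.27, 0.35, 0.54 and
0.52 °C/decade; precipitation carries no trend. Total planting area grows
linearly 1.95×10⁴ → 4.53×10⁴ km² (factor 2.32) with crop shares drifting
from the 1995 mix (≈45% wheat, 35% cotton, 19% corn) to the 2017 mix
(≈52% cotton, 25% wheat, 22% corn); per-region totals use fixed weights
dominated by the two largest dry-basin prefectures. Irrigation
efficiencies are the published per-prefecture values (provincial mean
0.68). Actual withdrawals are constructed as ia = iwr·(1+bias)+noise with
a default bias of −0.34, matching the ratio of reported withdrawal to
implied requirement in the benchmark year, so balance recovery is testable
and the default run exhibits the observed scarcity pattern.

Temperature is a seasonal sinusoid plus trend plus station-month Gaussian
noise (σ = 0.8 °C); precipitation is monthly gamma draws (shape 2) with a
summer-weighted profile; humidity is anti-correlated with the seasonal
temperature anomaly; sunshine is bounded by daylight hours. Random streams
are split per table (stations/meteo/areas/actuals) from the one scenario
seed, so regenerating one table never shifts another, and equal seeds give
byte-identical tables.

What the generator does *not* emulate: spatial autocorrelation beyond
archetype means, interannual precipitation regimes, station relocation or
inhomogeneity, multi-cropping, and real planting-area interannual
variability. Passing tests therefore demonstrate correctness of the
accounting and recoverability of configured signals, not statistical
fidelity to any particular province's observed record.

## Problem sizes

The default scenario is 66 stations × 23 years × 12 months (18,216
station-months), 15 regions × 3 crops × 23 years × 12 months (12,420
demand rows) and 345 region-year rows per crop for the attribution fit —
the full pipeline runs in seconds. Unit tests use a reduced scenario
(18 stations, 7 years) where the full one adds nothing.

## Known limitations

- Standard-condition ETc assumes disease-free, well-watered, fully
  producing crops; actual evapotranspiration under stress is lower, so IWR
  is an upper-bound requirement rather than observed use.
- A single effective-precipitation scalar ignores intensity and soil
  effects; a single Ie scalar per region subsumes all conveyance and
  application losses.
- Thiessen assignment is discontinuous at polygon boundaries and ignores
  orographic gradients between stations.
- The arithmetic identity checks among published headline values confirm
  internal consistency only; absolute reproduction of the published
  magnitudes would require the original station and yearbook records,
  which are not deposited.
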