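# cropwater

Regional crop irrigation water requirements and water balance for arid
irrigated provinces, estimated from monthly station meteorology and
yearbook planting areas.

`cropwater` is aimed at agro-hydrologists who need a transparent,
reproducible desk-scale answer to three questions: how much irrigation
water do the main crops of a region *require*, how does that requirement
move through time and space, and how does it compare with the water that
is actually withdrawn?

## Model

The chain is the standard single-crop-coefficient water accounting:

1. **Reference evapotranspiration** (FAO-56 Penman-Monteith), computed as a
   daily rate from monthly means and scaled by month length:

   ET₀ = [0.408 Δ (Rn − G) + γ · 900/(T+273) · u₂ (es − ea)] / [Δ + γ (1 + 0.34 u₂)]

   with all sub-terms (e°, Δ, γ, pressure from elevation, log-profile wind
   conversion, extraterrestrial and net radiation from latitude, month and
   sunshine hours, monthly soil heat flux) in their standard FAO-56 forms.

2. **Crop coefficients.** Each crop season has four stages (initial,
   development, mid, late). Tabulated standards Kc_ini/Kc_mid/Kc_end are
   climate-adjusted with Kc = Kc_std + [0.04(u₂−2) − 0.004(RHmin−45)](h/3)^0.3,
   where RHmin = e°(Tmin)/e°(Tmax) × 100%, then expanded into a
   piecewise-linear daily curve and averaged to months.

3. **Demand.** Per region-crop-month: Pe = δ·P (δ = 0.52),
   ETc = Kc·ET₀, CWR = max(ETc − Pe, 0), IWR = A·CWR/Ie with planting area A
   (km²) and per-region irrigation efficiency Ie.

4. **Regionalization.** Station series are carried onto regions by the
   Thiessen-polygon rule (nearest station per cropland cell, area-weighted).

5. **Balance & attribution.** ΔW = Ia − IWR per region-year (surplus /
   scarcity), OLS trends per basin, and a random-forest permutation
   importance of planting area vs temperature as drivers of IWR.

A first-class synthetic-data generator produces seeded station
meteorology, region geometries, planting areas, efficiencies and actual
withdrawals with the statistical structure the analysis assumes, so the
whole pipeline runs and is testable without any download.

## Worked example

```python
from cropwater import PipelineConfig, run_pipeline
from cropwater.demand import aggregate_iwr, crop_share

results = run_pipeline(PipelineConfig(seed=1), write=False)
totals = aggregate_iwr(results["demand"], by=("year",)).set_index("year")
print(round(totals.loc[1995, "iwr_billion_m3"], 2))   # 17.98
print(round(totals.loc[2017, "iwr_billion_m3"], 2))   # 45.05
print(round(crop_share(results["demand"], "cotton", 2017), 2))  # 59.18
```

On the default synthetic scenario the province-wide irrigation water
requirement grows from 17.98 to 45.05 billion m³ over 1995–2017, driven by
a 2.32× expansion of planting area with the crop mix drifting toward
cotton — which by 2017 accounts for 59.18% of the total requirement. The
hot dry basin archetype averages ≈1184 mm annual ET₀ against ≈796 mm in
the humid mountain-margin archetype, and with withdrawals generated 34%
below requirement every basin lands in scarcity.

The same pipeline is scriptable from the shell:

```sh
cropwater synth --seed 1 --out data/
cropwater et0 --stations data/meteo.csv --out et0.csv
cropwater run --seed 1 --out outputs/
```

Input schemas are plain CSV (see `configs/` for a pipeline config, crop
parameters and the shipped per-prefecture efficiency table); every stage
writes delimited text plus a `manifest.json` with the config hash, seed
and row counts.

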