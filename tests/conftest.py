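import numpy as np
import pandas as pd
import pytest

from cropwater.pipeline import PipelineConfig, run_pipeline
from cropwater.synthetic_data import SyntheticScenario, gen_monthly_meteo, gen_stations


@pytest.fixture(scope="session")
def small_scenario() -> SyntheticScenario:
    """A reduced scenario for fast unit-level pipeline runs."""
    return SyntheticScenario.xinjiang_like(seed=3, n_stations=18, years=(2000, 2006))


@pytest.fixture(scope="session")
def small_results(small_scenario):
    cfg = PipelineConfig(seed=small_scenario.seed)
    # reuse the reduced scenario rather than the default 66-station one
    from cropwater import pipeline as pl

    inputs = pl._load_inputs(cfg)
    inputs_small = {
        **inputs,
        "scenario": small_scenario,
        "stations": gen_stations(small_scenario),
    }
    inputs_small["meteo"] = gen_monthly_meteo(small_scenario, inputs_small["stations"])
    from cropwater.synthetic_data import efficiency_table, gen_crop_areas, gen_region_geometries

    inputs_small["regions"] = gen_region_geometries(small_scenario)
    inputs_small["areas"] = gen_crop_areas(small_scenario)
    inputs_small["efficiency"] = efficiency_table(small_scenario)
    inputs_small["basins"] = small_scenario.basins

    from cropwater import demand as dm
    from cropwater import meteo_et0 as me

    et0 = me.station_et0_series(inputs_small["meteo"])
    rc = pl.regionalize_climate(inputs_small["stations"], inputs_small["meteo"], et0, inputs_small["regions"])
    kc = pl.build_kc_table(rc)
    demand_table = dm.build_demand_table(
        rc, kc, inputs_small["areas"], inputs_small["efficiency"], inputs_small["basins"]
    )
    return {
        "scenario": small_scenario,
        "inputs": inputs_small,
        "et0": et0,
        "region_climate": rc,
        "kc": kc,
        "demand": demand_table,
    }


@pytest.fixture(scope="session")
def full_results():
    """One full default-scenario pipeline run shared by the acceptance suite."""
    return run_pipeline(PipelineConfig(seed=0), write=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
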