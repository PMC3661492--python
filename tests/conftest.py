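"""Shared fixtures: small synthetic fisheries and a cheaply fitted model."""
import numpy as np
import pandas as pd
import pytest

from bycatch import synthetic
from bycatch.hurdle import HurdleModel, McmcConfig


def small_scenario(n_years=2, tows_per_year=800, coverage=0.4):
    return synthetic.ScenarioConfig(
        n_years=n_years, first_year=2001,
        effort_by_year=(tows_per_year,) * n_years,
        coverage_by_year=(coverage,) * n_years)


@pytest.fixture(scope="session")
def mini_fishery():
    """A 2-year, 1600-tow fishery with hidden truth (seed 11)."""
    obs, truth, alphas = synthetic.simulate_fishery(small_scenario(), seed=11)
    return obs, truth, alphas


@pytest.fixture(scope="session")
def mid_fishery():
    """A 4-year, 4000-tow fishery with 50% coverage (seed 3)."""
    cfg = small_scenario(n_years=4, tows_per_year=1000, coverage=0.5)
    obs, truth, alphas = synthetic.simulate_fishery(cfg, seed=3)
    return obs, truth, alphas


@pytest.fixture(scope="session")
def fitted_mid(mid_fishery):
    """A short-chain fit of the hurdle model on the 4-year fishery."""
    obs, truth, alphas = mid_fishery
    model = HurdleModel.from_dataframe(obs)
    res = model.fit(McmcConfig(n_burn=1000, n_iter=4000, thin=10, seed=7))
    return res, truth, alphas


def make_effort_frame(n=3, **overrides):
    """A tiny, fully valid canonical effort frame."""
    base = pd.DataFrame({
        "tow_id": [f"T{i}" for i in range(n)],
        "vessel_id": ["V1"] * n,
        "vessel_length": [95.0] * n,
        "start_time": pd.date_range("2003-12-01 06:00", periods=n, freq="12h"),
        "end_time": pd.date_range("2003-12-01 10:00", periods=n, freq="12h"),
        "start_lat": [-38.5] * n,
        "start_lon": [172.0] * n,
        "end_lat": [-38.6] * n,
        "end_lon": [172.1] * n,
        "target_species": ["JMA"] * n,
        "catch_weight": [20.0] * n,
        "groundline_depth": [120.0] * n,
        "headline_height": [45.0] * n,
        "trawl_speed": [4.5] * n,
    })
    for k, v in overrides.items():
        base[k] = v
    return base
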