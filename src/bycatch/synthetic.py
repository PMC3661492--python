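"""Synthetic trawl-fleet generator with the statistical structure the
analysis assumes.

The default scenario emulates a 16-year large-vessel mackerel fishery: the
published annual effort and observer-coverage fractions, seven main vessels
sharing the effort evenly, a headline-depth mixture that is shallower on
night hauls (reproducing the real fishery's confounding of depth with light
condition), log-normal tow durations with a 4 h median, and capture counts
generated from the hurdle model itself with the published coefficient values
and a zero-truncated Poisson event size of 2.1.

Every generator is deterministic given its seed.  The hidden truth (capture
counts on *all* tows) is retained separately from the observable data set so
that estimator coverage can be evaluated.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import covariates as cov
from .effort import fishing_year_index
from .estimation import sample_ztp

__all__ = [
    "TABLE_EFFORT", "TABLE_COVERAGE", "TrueParams", "ScenarioConfig",
    "published_scenario", "generate_effort", "simulate_captures",
    "apply_observer_coverage", "simulate_fishery",
]

#: published annual effort (tows) for fishing years 1995-96 .. 2010-11
TABLE_EFFORT = (406, 230, 560, 350, 412, 974, 1577, 2249, 2309, 2424,
                2117, 2167, 2164, 1820, 2189, 1551)
#: published annual observer-coverage fractions for the same years
TABLE_COVERAGE = (0.296, 0.704, 0.389, 0.240, 0.172, 0.122, 0.070, 0.099,
                  0.071, 0.231, 0.306, 0.287, 0.340, 0.381, 0.301, 0.299)
#: published annual observed captures and capture events (replication inputs)
TABLE_CAPTURES = (2, 0, 0, 0, 1, 1, 1, 21, 17, 21, 2, 11, 20, 11, 4, 7)
TABLE_EVENTS = (1, 0, 0, 0, 1, 1, 1, 6, 7, 10, 1, 5, 5, 4, 2, 6)
FIRST_YEAR = 1995

#: monthly effort weights over the fishing year (Oct..Sep): effort peaks in
#: October and especially December, and is light over winter
MONTH_WEIGHTS = {10: 0.20, 11: 0.12, 12: 0.30, 1: 0.08, 2: 0.06, 3: 0.06,
                 4: 0.06, 5: 0.05, 6: 0.02, 7: 0.02, 8: 0.01, 9: 0.02}


@dataclass
class TrueParams:
    """Generative hurdle-model parameters (design-column keyed betas)."""

    beta: dict = field(default_factory=lambda: {
        "headline_depth": -0.033,
        "log_tow_duration": 1.470,
        "light_condition[light]": float(np.log(0.177)),
        "light_condition[black]": float(np.log(1.078)),
        "subarea[south]": float(np.log(0.539)),
    })
    mu_alpha: float = -4.5
    sigma_alpha: float = 0.6
    lam: float = 2.1
    year_alphas: np.ndarray | None = None  # drawn from the hierarchy if None


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic fishery."""

    n_years: int = 16
    first_year: int = FIRST_YEAR
    effort_by_year: tuple = TABLE_EFFORT
    coverage_by_year: tuple = TABLE_COVERAGE
    n_vessels: int = 7
    vessel_lengths: tuple = (95.0, 98.0, 100.0, 103.0, 105.0, 108.0, 112.0)
    p_night_haul: float = 0.30          # haul lands in the 21:00-06:00 block
    shallow_frac_night: float = 0.80    # shallow mixture weight, night hauls
    shallow_frac_day: float = 0.514     # chosen so the pooled weight is 0.60
    headline_shallow: tuple = (30.0, 15.0)   # mean, sd (m), truncated > 5
    headline_deep: tuple = (90.0, 40.0)
    duration_log_median: float = float(np.log(4.0))  # log-normal, median 4 h
    duration_log_sd: float = 0.35
    p_south: float = 0.45
    lat_range_north: tuple = (-39.3, -36.8)
    lat_range_south: tuple = (-40.9, -39.3)
    lon_range: tuple = (171.2, 172.9)
    true_params: TrueParams = field(default_factory=TrueParams)
    utc_offset: float = 12.0

    def __post_init__(self):
        if len(self.effort_by_year) != self.n_years or \
           len(self.coverage_by_year) != self.n_years:
            raise ValueError("effort and coverage must list one value per year")
        if any(not 0 <= c <= 1 for c in self.coverage_by_year):
            raise ValueError("coverage fractions must lie in [0, 1]")
        if len(self.vessel_lengths) != self.n_vessels:
            raise ValueError("one length per vessel required")

    @property
    def total_effort(self) -> int:
        return int(sum(self.effort_by_year))


def published_scenario() -> ScenarioConfig:
    """The default 16-year scenario (23 499 tows; published effort/coverage)."""
    return ScenarioConfig()


def _truncated_normal(rng, mean, sd, lo, size):
    out = rng.normal(mean, sd, size)
    while True:
        bad = out <= lo
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))


def generate_effort(config: ScenarioConfig | None = None, seed: int = 0
                    ) -> pd.DataFrame:
    """Generate the fisher-reported effort records (no captures yet)."""
    cfg = config or published_scenario()
    rng = np.random.default_rng(seed)
    months = np.array(list(MONTH_WEIGHTS))
    month_p = np.array(list(MONTH_WEIGHTS.values()))
    month_p = month_p / month_p.sum()

    frames = []
    for yi in range(cfg.n_years):
        year = cfg.first_year + yi
        n = int(cfg.effort_by_year[yi])
        vessel = rng.integers(0, cfg.n_vessels, size=n)
        m = rng.choice(months, size=n, p=month_p)
        cal_year = np.where(m >= 10, year, year + 1)
        days_in = pd.to_datetime({"year": cal_year, "month": m, "day": 1}) \
            .dt.days_in_month.to_numpy()
        day = rng.integers(1, days_in + 1)
        night = rng.random(n) < cfg.p_night_haul
        # haul-time (end of tow) local hour: night block 21:00-06:00
        hour = np.where(night,
                        (21.0 + 9.0 * rng.random(n)) % 24.0,
                        6.0 + 15.0 * rng.random(n))
        end = (pd.to_datetime({"year": cal_year, "month": m, "day": day})
               + pd.to_timedelta(np.round(hour * 3600).astype(int), unit="s"))
        duration_h = np.exp(rng.normal(cfg.duration_log_median,
                                       cfg.duration_log_sd, n))
        duration_h = np.clip(duration_h, 0.5, 12.0)
        start = end - pd.to_timedelta(np.round(duration_h * 3600).astype(int),
                                      unit="s")
        # keep the whole tow inside its fishing year (1 Oct - 30 Sep)
        fy_start = pd.Timestamp(year=year, month=10, day=1)
        early = start < fy_start
        if early.any():
            shift = pd.to_timedelta(np.where(early, 1, 0), unit="D")
            start = start + shift
            end = end + shift

        p_shallow = np.where(night, cfg.shallow_frac_night, cfg.shallow_frac_day)
        shallow = rng.random(n) < p_shallow
        headline_depth = np.where(
            shallow,
            _truncated_normal(rng, *cfg.headline_shallow, 5.0, n),
            _truncated_normal(rng, *cfg.headline_deep, 5.0, n))
        headline_height = _truncated_normal(rng, 45.0, 8.0, 20.0, n)
        groundline = headline_depth + headline_height

        south = rng.random(n) < cfg.p_south
        lat_lo = np.where(south, cfg.lat_range_south[0], cfg.lat_range_north[0])
        lat_hi = np.where(south, cfg.lat_range_south[1], cfg.lat_range_north[1])
        lat = lat_lo + (lat_hi - lat_lo) * rng.random(n)
        lon = cfg.lon_range[0] + np.diff(cfg.lon_range)[0] * rng.random(n)
        dlat = rng.normal(0, 0.02, n)
        dlon = rng.normal(0, 0.02, n)

        target = rng.choice(["JMA", "EMA", "BAR"], size=n, p=[0.88, 0.07, 0.05])
        catch = np.exp(rng.normal(np.log(25.0), 0.8, n))
        speed = rng.normal(4.5, 0.5, n)
        week = pd.DatetimeIndex(start).isocalendar().week.to_numpy()
        trip = [f"V{v}-{year}-{w // 2}" for v, w in zip(vessel, week)]

        frames.append(pd.DataFrame({
            "tow_id": [f"T{year}-{i:05d}" for i in range(n)],
            "vessel_id": [f"V{v}" for v in vessel],
            "vessel_length": np.array(cfg.vessel_lengths)[vessel],
            "start_time": start, "end_time": end,
            "start_lat": lat, "start_lon": lon,
            "end_lat": np.clip(lat + dlat, lat_lo, lat_hi),
            "end_lon": lon + dlon,
            "target_species": target,
            "catch_weight": np.round(catch, 2),
            "groundline_depth": np.round(groundline, 1),
            "headline_height": np.round(headline_height, 1),
            "trawl_speed": np.round(speed, 2),
            "bottom_depth": np.round(groundline + 20.0 + rng.exponential(50.0, n), 1),
            "trip_id": trip,
        }))
    out = pd.concat(frames, ignore_index=True)
    out["observed"] = False
    out["captures"] = np.nan
    return out


def simulate_captures(tows: pd.DataFrame, params: TrueParams | None = None,
                      seed: int = 0, utc_offset: float = 12.0):
    """Draw ground-truth capture counts for every tow from the hurdle model.

    Returns ``(frame with captures_true on all tows, year_alphas)``; the
    frame also carries the derived covariate columns.
    """
    params = params or TrueParams()
    rng = np.random.default_rng(seed)
    df = cov.derive_covariates(tows, utc_offset=utc_offset)
    design = cov.build_design_matrix(df, cov.default_model_specs())
    X = design.X
    beta = np.array([params.beta.get(c, 0.0) for c in X.columns])
    n_years = len(design.year_levels)
    alphas = params.year_alphas
    if alphas is None:
        alphas = params.mu_alpha + params.sigma_alpha * rng.standard_normal(n_years)
    alphas = np.asarray(alphas, dtype=float)
    eta = alphas[design.year_index] + X.to_numpy() @ beta
    p = expit(eta)
    event = rng.random(len(p)) < p
    counts = np.zeros(len(p))
    n_ev = int(event.sum())
    if n_ev:
        counts[event] = sample_ztp(params.lam, rng, size=n_ev)
    out = design.frame.copy()
    out["captures_true"] = counts.astype(int)
    out["event_probability"] = p
    return out, alphas


def apply_observer_coverage(tows: pd.DataFrame, coverage_by_year=None,
                            seed: int = 0):
    """Flag a per-year simple random sample of tows as observed.

    Capture counts are exposed only on observed tows; the returned ``truth``
    frame keeps the counts on every tow for later evaluation.
    """
    cfg_cov = TABLE_COVERAGE if coverage_by_year is None else coverage_by_year
    rng = np.random.default_rng(seed)
    df = tows.copy()
    if "fishing_year" not in df.columns:
        df["fishing_year"] = fishing_year_index(df["start_time"])
    years = sorted(df["fishing_year"].unique())
    if np.isscalar(cfg_cov):
        cfg_cov = [float(cfg_cov)] * len(years)
    if len(cfg_cov) != len(years):
        raise ValueError("one coverage fraction per fishing year required")
    observed = np.zeros(len(df), dtype=bool)
    for y, frac in zip(years, cfg_cov):
        idx = np.flatnonzero((df["fishing_year"] == y).to_numpy())
        n_obs = int(round(len(idx) * float(frac)))
        if n_obs:
            observed[rng.choice(idx, size=n_obs, replace=False)] = True
    truth = df.copy()
    truth["observed"] = observed
    observable = df.copy()
    observable["observed"] = observed
    observable["captures"] = np.where(observed,
                                      truth["captures_true"].to_numpy(float),
                                      np.nan)
    observable = observable.drop(columns=["captures_true", "event_probability"],
                                 errors="ignore")
    return observable, truth


def simulate_fishery(config: ScenarioConfig | None = None, seed: int = 0):
    """End-to-end scenario: effort, true captures, partial observation.

    Returns ``(observable, truth, year_alphas)``.  Sub-seeds for the three
    stages are drawn from a seeded sequence, so a single integer reproduces
    the whole fishery.
    """
    cfg = config or published_scenario()
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    eff = generate_effort(cfg, seed=seeds[0])
    truth_frame, alphas = simulate_captures(eff, cfg.true_params, seed=seeds[1],
                                            utc_offset=cfg.utc_offset)
    observable, truth = apply_observer_coverage(
        truth_frame, cfg.coverage_by_year, seed=seeds[2])
    return observable, truth, alphas
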