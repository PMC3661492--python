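"""Extrapolation of captures to unobserved effort and result summaries.

For each posterior draw, every unobserved tow gets a simulated capture event
(Bernoulli with its modelled probability) and, given an event, a
zero-truncated Poisson event size; group totals are the observed captures plus
the simulated unobserved ones.  Intervals are equal-tailed posterior
quantiles.  The same posterior draw supplies both the event probability and
the event-size parameter, so their joint uncertainty propagates into totals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import poisson

__all__ = [
    "sample_ztp", "ztp_mean", "lambda_from_event_mean",
    "GroupTotals", "predict_group_totals", "annual_summary_table",
    "capture_rate_per_100", "halving_distance", "ppc_event_size",
]


def ztp_mean(lam):
    """Mean of the zero-truncated Poisson: lam / (1 - e^-lam)."""
    lam = np.asarray(lam, dtype=float)
    out = lam / -np.expm1(-lam)
    return float(out) if out.ndim == 0 else out


def lambda_from_event_mean(mean: float, bounds=(0.5, 30.0)) -> float:
    """Solve the ZTP mean identity lam/(1-e^-lam) = mean for lam by bisection.

    ``mean`` is the average number of animals per capture event; the solution
    is searched inside ``bounds`` (the model's uniform prior support).
    """
    lo, hi = bounds
    f = lambda l: ztp_mean(l) - mean
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(f"event mean {mean} has no ZTP size in {bounds}")
    return float(brentq(f, lo, hi, xtol=1e-10))


def sample_ztp(lam, rng: np.random.Generator, size=None):
    """Exact zero-truncated Poisson draws via the inverse CDF.

    The uniform variate is mapped into the conditional-on-positive region of
    the Poisson CDF, so no rejection loop is needed.
    """
    lam = float(lam)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    u = rng.random(size)
    p0 = np.exp(-lam)
    n = poisson.ppf(p0 + u * (1.0 - p0), lam)
    n = np.maximum(n, 1.0)
    return int(n) if size is None else n.astype(int)


@dataclass
class GroupTotals:
    """Per-group posterior totals: ``draws`` is (n_draws, n_groups)."""

    keys: pd.DataFrame            # one row per group (year label, vessel, ...)
    draws: np.ndarray             # posterior total captures per group
    observed_captures: np.ndarray
    observed_tows: np.ndarray
    total_tows: np.ndarray

    def summary(self) -> pd.DataFrame:
        q = np.percentile(self.draws, [2.5, 50, 97.5], axis=0)
        rates = 100.0 * self.draws / np.maximum(self.total_tows, 1)[None, :]
        rq = np.percentile(rates, [2.5, 97.5], axis=0)
        out = self.keys.copy()
        out["total_tows"] = self.total_tows
        out["observed_tows"] = self.observed_tows
        out["observed_captures"] = self.observed_captures
        out["est_mean"] = self.draws.mean(axis=0)
        out["est_2.5"] = q[0]
        out["est_50"] = q[1]
        out["est_97.5"] = q[2]
        out["rate_mean"] = rates.mean(axis=0)
        out["rate_2.5"] = rq[0]
        out["rate_97.5"] = rq[1]
        return out

    def aggregate_years(self) -> "GroupTotals":
        """Sum vessel groups to year totals, draw by draw."""
        if "fishing_year_label" not in self.keys.columns:
            raise ValueError("no fishing_year_label key to aggregate on")
        lab = self.keys["fishing_year_label"]
        order = list(dict.fromkeys(lab))
        idx = {y: i for i, y in enumerate(order)}
        codes = lab.map(idx).to_numpy()
        n_y = len(order)

        def agg(v):
            return np.stack([v[:, codes == i].sum(axis=1) for i in range(n_y)], axis=1) \
                if v.ndim == 2 else np.bincount(codes, weights=v, minlength=n_y)

        return GroupTotals(
            keys=pd.DataFrame({"fishing_year_label": order}),
            draws=agg(self.draws),
            observed_captures=agg(self.observed_captures),
            observed_tows=agg(self.observed_tows),
            total_tows=agg(self.total_tows),
        )


def predict_group_totals(results, design=None, by=("fishing_year_label",),
                         seed: int = 0, max_draws: int | None = None) -> GroupTotals:
    """Posterior totals of captures per group over *all* effort.

    Parameters
    ----------
    results : HurdleResults
    design : DesignMatrix, optional
        Defaults to the design the model was built from (which must then
        include the unobserved tows).
    by : tuple of frame columns
        Grouping key, e.g. ``("fishing_year_label", "vessel_id")``.
    seed : int
        Seed for the prediction-side simulation.
    max_draws : int, optional
        Subsample of posterior draws to use (all by default).
    """
    design = design or results.model.design
    frame = design.frame
    missing = design.X.isna().any(axis=1)
    if missing.any():
        raise ValueError(f"unobserved tows with missing covariates: rows "
                         f"{list(frame.index[missing])[:10]}")
    keys_all = frame[list(by)].astype(str)
    key_df = keys_all.drop_duplicates().sort_values(list(by)).reset_index(drop=True)
    code_of = {tuple(r): i for i, r in enumerate(key_df.itertuples(index=False))}
    codes = np.array([code_of[tuple(r)] for r in keys_all.itertuples(index=False)])
    n_groups = len(key_df)

    obs = design.observed.astype(bool)
    counts_obs = np.where(obs, np.nan_to_num(design.counts), 0.0)
    O = np.bincount(codes, weights=counts_obs, minlength=n_groups)
    obs_tows = np.bincount(codes[obs], minlength=n_groups)
    tot_tows = np.bincount(codes, minlength=n_groups)

    stacked = results.posterior.stacked()
    rng = np.random.default_rng(seed)
    if max_draws is not None and max_draws < len(stacked):
        pick = rng.choice(len(stacked), size=max_draws, replace=False)
        stacked = stacked[np.sort(pick)]
    k = results.model.k
    T = results.model.n_years
    un = ~obs
    Xu = design.X.to_numpy(dtype=float)[un]
    yearu = design.year_index[un]
    codes_u = codes[un]
    n_un = int(un.sum())

    draws_tot = np.tile(O, (len(stacked), 1))
    for d, v in enumerate(stacked):
        if n_un == 0:
            break
        beta = v[:k]
        alpha = v[k:k + T]
        lam = v[-1]
        p = expit(alpha[yearu] + Xu @ beta)
        ev = rng.random(n_un) < p
        n_ev = int(ev.sum())
        if n_ev:
            sizes = sample_ztp(lam, rng, size=n_ev)
            draws_tot[d] += np.bincount(codes_u[ev], weights=sizes.astype(float),
                                        minlength=n_groups)
    return GroupTotals(keys=key_df, draws=draws_tot, observed_captures=O,
                       observed_tows=obs_tows, total_tows=tot_tows)


def capture_rate_per_100(captures, tows):
    """Captures per 100 tows; NaN when the denominator is zero."""
    tows = float(tows)
    c = np.asarray(captures, dtype=float)
    if tows == 0:
        out = np.full(c.shape, np.nan)
        return float("nan") if c.ndim == 0 else out
    out = 100.0 * c / tows
    return float(out) if out.ndim == 0 else out


def halving_distance(beta_headline: float) -> float:
    """Headline-depth increase (m) that halves the capture-event odds.

    For a log-odds coefficient b < 0 the odds halve every ln(2)/|b| metres;
    with event probabilities far below one this is also the halving distance
    of the probability itself.
    """
    if beta_headline >= 0:
        raise ValueError("halving distance requires a negative coefficient")
    return float(np.log(2.0) / abs(beta_headline))


def annual_summary_table(year_totals: GroupTotals) -> pd.DataFrame:
    """Annual summary: effort, coverage, observed captures and rate, and
    estimated captures and rate per 100 tows (means with 95% intervals)."""
    s = year_totals.summary()
    out = pd.DataFrame({
        "fishing_year": s["fishing_year_label"],
        "effort_tows": s["total_tows"].astype(int),
        "pct_observed": 100.0 * s["observed_tows"] / s["total_tows"],
        "observed_captures": s["observed_captures"].astype(int),
        "observed_rate": np.where(
            s["observed_tows"] > 0,
            100.0 * s["observed_captures"] / s["observed_tows"].replace(0, np.nan),
            np.nan),
        "est_captures_mean": s["est_mean"],
        "est_captures_2.5": s["est_2.5"],
        "est_captures_97.5": s["est_97.5"],
        "est_rate_mean": s["rate_mean"],
        "est_rate_2.5": s["rate_2.5"],
        "est_rate_97.5": s["rate_97.5"],
    })
    return out


def ppc_event_size(results, observed_counts, seed: int = 0,
                   max_draws: int = 1000) -> pd.DataFrame:
    """Posterior predictive check of the captures-per-event distribution.

    For each posterior draw, the observed number of events is re-simulated
    from ZTP(lambda_draw) and tallied by event size; the table reports the
    2.5/25/50/75/97.5% bands of those tallies against the observed tally.
    """
    obs = np.asarray(observed_counts, dtype=int)
    if obs.size == 0 or np.any(obs < 1):
        raise ValueError("need at least one observed event, all sizes >= 1")
    lam_draws = results.lambda_draws()
    rng = np.random.default_rng(seed)
    if len(lam_draws) > max_draws:
        lam_draws = lam_draws[np.sort(rng.choice(len(lam_draws), max_draws,
                                                 replace=False))]
    n_ev = obs.size
    max_size = int(max(obs.max(), 1))
    tallies = []
    for l in lam_draws:
        sizes = sample_ztp(l, rng, size=n_ev)
        max_size = max(max_size, int(sizes.max()))
        tallies.append(sizes)
    table = np.zeros((len(tallies), max_size), dtype=float)
    for d, sizes in enumerate(tallies):
        bc = np.bincount(sizes, minlength=max_size + 1)[1:max_size + 1]
        table[d] = bc
    q = np.percentile(table, [2.5, 25, 50, 75, 97.5], axis=0)
    obs_tab = np.bincount(obs, minlength=max_size + 1)[1:max_size + 1]
    out = pd.DataFrame({
        "size": np.arange(1, max_size + 1),
        "observed": obs_tab,
        "q2.5": q[0], "q25": q[1], "q50": q[2], "q75": q[3], "q97.5": q[4],
    })
    out["outside_band"] = (out["observed"] < out["q2.5"]) | \
                          (out["observed"] > out["q97.5"])
    return out


def plot_ppc_event_size(ppc: pd.DataFrame, path=None):
    """Boxplot-style rendering of :func:`ppc_event_size` (observed as a line)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    x = ppc["size"]
    ax.fill_between(x, ppc["q2.5"], ppc["q97.5"], alpha=0.2, label="95% band")
    ax.fill_between(x, ppc["q25"], ppc["q75"], alpha=0.35, label="quartiles")
    ax.plot(x, ppc["q50"], lw=1, label="predicted median")
    ax.plot(x, ppc["observed"], "k-o", ms=4, label="observed")
    ax.set_xlabel("captures per event")
    ax.set_ylabel("number of events")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
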