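# bycatch

Bayesian hurdle-model estimation of protected-species bycatch in partially
observed trawl fisheries.

Trawl fleets that overlap with dolphin habitat catch animals incidentally, but
government observers ride only a fraction of tows. This package estimates
**total** captures — including those on unobserved tows — from fisher-reported
effort records and observer capture records, and identifies the operational
covariates (gear depth, tow timing, light conditions, area) associated with
capture risk. It was built around the common-dolphin bycatch problem in a
large-vessel mackerel trawl fishery (16 fishing years, ~23 500 tows, observer
coverage fluctuating between 7% and 70%), with a synthetic fleet generator
standing in for the confidential fishery data.

## The model

Capture *events* and event *sizes* are modelled separately (a hurdle model),
because different processes govern whether dolphins encounter the net and how
many are caught when they do.

**Stage 1 — capture events.** The probability $p_i$ of a capture event on tow
$i$ in fishing year $t(i)$ follows a hierarchical logistic regression

$$\operatorname{logit} p_i = \alpha_{t(i)} + \sum_k \beta_k x_{ik},
\qquad \alpha_t \sim \mathcal N(\mu_\alpha, \sigma_\alpha^2),$$

with covariates $x_{ik}$ (headline depth in metres, log tow duration, light
condition, sub-area) and exchangeable year effects absorbing annual variation
unrelated to the covariates.

**Stage 2 — event sizes.** Given an event, the number of animals $n \ge 1$
follows a zero-truncated Poisson,

$$P(n \mid \lambda) = \frac{\lambda^{n} e^{-\lambda}}{n!\,(1 - e^{-\lambda})}.$$

**Priors.** $\beta_k, \mu_\alpha \sim \mathcal N(0, 100^2)$,
$\sigma_\alpha \sim \text{half-Cauchy}(25)$, $\lambda \sim U(0.5, 30)$.

**Estimation of totals.** For group $g$ (a fishing year, or year × vessel),
total captures are $C_g = O_g + U_g$: observed captures $O_g$ plus captures
$U_g$ simulated on the unobserved tows from each posterior draw
(Bernoulli$(p_i)$ events, zero-truncated Poisson sizes). Equal-tailed
2.5%/97.5% posterior quantiles give 95% credible intervals; rates are
$100\,C_g/\text{tows}_g$.

Covariates are screened beforehand with a stepwise binomial GLM: at each step
the addition/removal with the greatest AIC reduction is taken, and the search
stops when the best addition no longer reduces the residual deviance by more
than 1%.

## Worked example

```python
from bycatch import (simulate_fishery, HurdleModel, McmcConfig,
                     predict_group_totals, annual_summary_table,
                     halving_distance)

# a synthetic 4-year fishery: 1000 tows/year, 50% observer coverage
from bycatch.synthetic import ScenarioConfig
cfg = ScenarioConfig(n_years=4, first_year=2001,
                     effort_by_year=(1000,) * 4, coverage_by_year=(0.5,) * 4)
observable, truth, _ = simulate_fishery(cfg, seed=3)

model = HurdleModel.from_dataframe(observable)
res = model.fit(McmcConfig(n_burn=2000, n_iter=10_000, thin=10, seed=7))
print(res.coefficient_table().round(3))
years = predict_group_totals(res, seed=1).summary()
print(years[["fishing_year_label", "observed_captures",
             "est_mean", "est_2.5", "est_97.5"]].round(1))
beta = res.coefficient_table().loc["headline_depth", "mean"]
print(f"halving distance: {halving_distance(beta):.1f} m")
print(f"hidden true total: {truth.captures_true.sum()}")
```

prints

```
                         mean   2.5%    50%  97.5%
headline_depth         -0.044 -0.080 -0.043 -0.016
log_tow_duration        1.810  0.326  1.794  3.309
light_condition[light]  0.179  0.052  0.158  0.436
light_condition[black]  0.464  0.010  0.283  1.916
subarea[south]          0.402  0.087  0.346  1.067
  fishing_year_label  observed_captures  est_mean  est_2.5  est_97.5
0            2001-02                1.0       4.8      1.0      16.0
1            2002-03                8.0      15.4      8.0      30.0
2            2003-04                6.0      12.6      6.0      26.0
3            2004-05               17.0      33.5     20.0      54.0
halving distance: 15.7 m
hidden true total: 81
```

The factor coefficients are exponentiated (multiplicative effects relative to
the reference level: hauls in the dark, northern sub-area), so hauling in
daylight or moonlight carries roughly one-fifth the capture-event odds of a
dark-night haul. The posterior mean headline-depth coefficient of −0.044 m⁻¹
implies that towing the headline ~16 m deeper halves the event odds, and the
hidden true total (81) lies inside the summed annual 95% intervals.

The same pipeline runs from the shell:

```bash
bycatch simulate --config scenario.yaml --seed 5 --outdir run/
bycatch prepare  --outdir run/
bycatch select   --outdir run/
bycatch fit      --outdir run/ --seed 5
bycatch estimate --outdir run/ --seed 5
bycatch report   --outdir run/
```

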