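# Methods

## Model

The package estimates total incidental captures of a protected species in a
trawl fishery in which only a fraction of tows carry an observer. The
response on each *observed* tow is the capture count; unobserved tows have an
*undefined* (not zero) count. A two-stage hurdle structure separates the two
processes at work:

1. **Capture events.** A hierarchical logistic regression gives the
   probability `p_i` that tow `i` has at least one capture:
   `logit p_i = alpha_t(i) + sum_k beta_k x_ik`, with one random effect
   `alpha_t ~ N(mu_alpha, sigma_alpha^2)` per fishing year (1 October–30
   September). Year effects absorb annual variation — prey distribution,
   dolphin abundance — that the operational covariates cannot explain.
2. **Event sizes.** Given an event, the count follows a zero-truncated
   Poisson (ZTP) with size `lambda`, constant across tows: exploratory
   covariate-dependence of the event size is out of scope here, and the
   hurdle structure makes the two stages a priori independent (their
   likelihoods factorize, which the tests exploit).

Assumptions worth stating: captures on distinct tows are independent given
the covariates and year effects; observer assignment is ignorable
(observed tows are exchangeable with unobserved ones within a year given the
covariates); the covariates recorded by fishers are available on *all* tows,
which is what makes extrapolation possible.

**Priors.** Deliberately uninformative: `N(0, 100^2)` on every
regression-scale parameter (`beta_k`, `mu_alpha`), half-Cauchy with scale 25
on `sigma_alpha`, and `U(0.5, 30)` on `lambda`. The half-Cauchy is placed on
the *standard deviation* of the year effects (the weakly-informative default
recommended for hierarchical scale parameters), and is configurable via
`PriorSpec`.

**Totals.** For each posterior draw and each unobserved tow, an event is
simulated as Bernoulli(`p_i`) and its size as ZTP(`lambda`); group totals are
`C_g = O_g + U_g` (observed plus simulated). The same draw supplies `p` and
`lambda`, so parameter uncertainty propagates jointly. Intervals are
equal-tailed 2.5/97.5% posterior quantiles; rates divide by *total* group
effort ("per 100 tows"), not by unobserved effort. Year totals are
draw-by-draw sums of year × vessel totals, so additivity holds exactly.

## Covariates

All covariates derive from fisher-reported fields:

| covariate | definition | default in model |
|---|---|---|
| headline depth (m) | groundline depth − headline height | yes (linear) |
| tow duration (h) | end − start | yes (log, no offset) |
| light condition | 3-level factor, reference **dark** | yes |
| sub-area | north/south of 39°18′S, reference **north** | yes |
| night hours (h) | tow time between civil dusk and dawn | candidate |
| catch weight (t), speed, depths, moon fraction, season | — | candidates |

Log transforms of catch weight and night hours add an offset of one tonne /
one hour first (both can be zero); duration is strictly positive and gets a
plain log.

**Light condition** classifies the *haul* (tow end) instant: `light` between
civil dawn and dusk, or between dusk and local midnight on a moonlit night;
`dark` between dusk and midnight on a dark night, or between midnight and
dawn on a moonlit night; `black` between midnight and dawn on a dark night.
A night is *moonlit* when the lunar disc is strictly more than 17%
illuminated at the haul time; midnight is 00:00 local civil time (haul times
are recorded in clock time). Civil dawn/dusk are the instants the sun's
centre crosses 6° below the horizon.

The "night hours" covariate counts tow hours between civil dusk and the next
civil dawn, summed over the (at most two) nights a tow touches. The covariate
is named for night time even though an alternative reading of its customary
description ("hours between dawn and dusk") would be daylight; the night
reading matches the covariate's name and its role alongside light condition.

**Ephemeris.** Solar position and lunar illuminated fraction come from
low-precision closed-form series (solar elevation accurate to ~0.01°, lunar
fraction to ~0.001 against a full-series reference): far more accuracy than a
6° crossing or a 17% threshold requires. Twilight instants are found by
vectorized bisection (40 halvings of a 12 h bracket ≈ 10 µs resolution;
agreement with the reference tables is within seconds). No atmospheric
refraction or ΔT corrections are applied. Latitudes beyond ±66° are rejected
rather than mis-handled.

**Bottom depth**, when no per-tow sounding exists, is looked up from a
plain-text regular raster as the minimum of the nearest-cell depths at the
tow's start and end positions; "shallow" means strictly less than 210 m.

## Covariate selection

A maximum-likelihood binomial GLM (logit link, IRLS) is refitted with each
candidate added or removed in turn, taking the move with the greatest AIC
reduction. The search starts from the intercept-only model, and a covariate
and its log-transform are never admitted together (they share a source field
and are near-collinear). The search ends when no move improves the AIC or
when the best addition's *relative residual-deviance reduction* is ≤ 1%; a
sub-1% addition is **rejected**, not kept — the deviance requirement exists
to prevent the inclusion of covariates with little explanatory power, and
this veto reading is also what makes all-noise candidate pools yield an empty
selection. Year effects are not included during screening: selection
addresses the fixed covariates, the hierarchy is fitted afterwards.

A caveat the acceptance tests quantify: for a covariate whose deviance
contribution sits near the 1% threshold (posterior z ≈ 2), the
repeated-sampling probability of selection is intrinsically around 50–60%.
A single realized selection of such a covariate in one data set is therefore
not a repeatable property, and the selection-power test documents exactly
this: the strongly supported covariates (headline depth family, light
condition) are recovered in nearly every replicate, while the weak sub-area
term is recovered in roughly half.

## Sampling

Componentwise adaptive random-walk Metropolis-within-Gibbs, implemented
directly (the likelihood bookkeeping updates the linear predictor
incrementally: O(n) per coefficient update, O(n_t) per year effect, O(1) for
`lambda`, which makes full-schedule runs cheap). Schedule defaults: 10 000
burn-in iterations, 100 000 further iterations thinned every 20th, two
chains — 5000 stored draws per chain. Specifics:

- proposals are Gaussian; `sigma_alpha` is updated on the log scale (with the
  Jacobian term), `lambda` on its natural scale with reflection at the
  uniform bounds (reflection keeps the proposal symmetric);
- proposal scales adapt every 50 burn-in iterations toward a 0.2–0.5
  acceptance band (×1.5 or ÷1.5) and are frozen at the end of burn-in, so the
  retained chain is a valid time-homogeneous Markov chain;
- chain `c` uses seed `seed + c`; starts are jittered around data-driven
  initial values (`beta = 0`, `alpha_t = mu_alpha = logit` of the observed
  event rate, `sigma_alpha = 1`, `lambda =` mean count among events);
- years with no observed tows draw their `alpha_t` from the hierarchy alone —
  prediction for them is pure extrapolation and their posteriors reproduce
  the prior hierarchy.

Convergence is monitored by plain split-R̂ (floored at 1; the rank-normalized
variant is deliberately not the default) and an autocorrelation ESS with
Geyer-style truncation at the first negative even/odd pair sum. Both are
cross-checked against an independent implementation in the tests. A
posterior-predictive check re-simulates the observed number of events from
each draw's ZTP and compares the tally per event size with the observed tally
(quartile and 95% bands).

## Synthetic fleet generator

The generator exists so that every stage is testable without confidential
data. It emulates:

- the published annual effort (406 … 1551 tows; 23 499 in total over 16
  years) and annual observer-coverage fractions (7–70%);
- seven main vessels (95–112 m) sharing effort evenly; trips of roughly
  two-week blocks; mostly mackerel targets with occasional other species;
- effort concentrated in October and December, hauls on a diel cycle with 30%
  of hauls in the 21:00–06:00 block;
- headline depth as a two-component mixture (60% shallow ~N(30, 15²), 40%
  deep ~N(90, 40²), truncated above 5 m), *coupled to haul time* — night
  hauls draw from the shallow component with probability 0.80 vs 0.514 by
  day — reproducing the real fleet's confounding of depth with light
  condition;
- log-normal tow durations (median 4 h), positions uniform within the
  rectangular study area with a 45% southern share;
- capture counts generated from the hurdle model itself with the published
  coefficient values (headline −0.033 m⁻¹; log-duration 1.470; light, black
  and south factors ln 0.177, ln 1.078, ln 0.539) and `lambda` = 2.1.

The year-effect hyperparameters are not published; `mu_alpha = −4.5`,
`sigma_alpha = 0.6` were fixed once so that the marginal event rate matches
the study's ~0.88 capture events per 100 tows, and then left alone.
Observer coverage is a per-year simple random sample without replacement
(trip-clustered coverage exists as a config option, off by default).

What the generator does **not** emulate — and hence what passing tests do not
establish about real data: spatial school structure and the shoreward
concentration of captures; vessel-specific behaviour (effort shares are even
and there is no vessel effect in the generative model); trip-level clustering
of observer deployments; reporting errors in times and positions (records are
clean by construction); and the real marginal distribution of headline depth,
for which the configured mixture is a stylized stand-in.

## Numerical and design choices

- ZTP log-pmf uses `log(-expm1(-lambda))`, stable as `lambda → 0`; ZTP
  sampling is exact inverse-CDF through the Poisson quantile function.
- The ZTP size implied by a mean count per event solves
  `lambda/(1−e^{−lambda}) = mean` by bisection on the prior support.
- Boundary conventions: the sub-area split latitude itself is **south**;
  "shallow" is strictly < 210 m; moonlit is strictly > 0.17; fishing-year
  labels are "1995-96"-style with the October start.
- Trips, when no trip identifier is supplied, are maximal runs of a vessel's
  tows with inter-tow gaps under 7 days.
- Observer–effort linking requires the same vessel and target species, start
  times within 60 min and positions within 10 km (great-circle); several
  qualifying tows resolve to the nearest in time, and two observer records
  claiming one tow raise an ambiguity error.
- The vessel-flag ("nation") covariate of the original candidate list is
  omitted: the canonical effort schema carries no flag field.
- Quasi-separation in the screening GLM is flagged at |coefficient| > 30 and
  such candidates are skipped during stepping; singular designs name the
  collinear columns.
- Test problem sizes are deliberately modest: recovery experiments use
  4-year, 4000-tow fisheries with short chains (20 replicates), the
  selection-power experiment 5-year, 5000-tow fisheries (50 replicates), and
  the full published scale is exercised by a single end-to-end replicate.

## Known limitations

- Ignorable-observation is assumed, not tested: if observers were assigned to
  tows with systematically different risk, extrapolation would be biased.
- The rectangular study region stands in for the true EEZ-bounded polygon.
- `lambda` is constant; covariate-dependent event sizes, negative-binomial
  and zero-inflated alternatives are out of scope.
- Posterior summaries for years without observed effort are hierarchy-only
  extrapolations.
- The stepwise procedure's 1% rule trades power for parsimony; see the
  selection caveat above.
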