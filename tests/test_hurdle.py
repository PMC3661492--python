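"""Hurdle-model likelihood, priors, and the MCMC fit."""
import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from bycatch import covariates as cov
from bycatch.hurdle import (HurdleModel, HurdleParams, McmcConfig, PriorSpec,
                            PosteriorSamples, capture_probability, ztp_log_pmf)
from conftest import make_effort_frame


def _params(beta, alpha, mu=0.0, sigma=1.0, lam=2.1):
    return HurdleParams(beta=np.asarray(beta, dtype=float),
                        alpha=np.asarray(alpha, dtype=float),
                        mu_alpha=mu, sigma_alpha=sigma, lam=lam)


def _toy_model(n=200, seed=0, p_event=0.3, n_years=2):
    """A small fully observed hurdle data set on one covariate."""
    rng = np.random.default_rng(seed)
    f = make_effort_frame(n)
    f["start_time"] = pd.date_range("2003-11-01 06:00", periods=n, freq="7h")
    f["end_time"] = f["start_time"] + pd.Timedelta("4h")
    if n_years > 1:
        half = n // 2
        f.loc[half:, "start_time"] += pd.DateOffset(years=1)
        f.loc[half:, "end_time"] += pd.DateOffset(years=1)
    x = rng.standard_normal(n)
    f["xcov"] = x
    f["observed"] = True
    event = rng.random(n) < p_event
    counts = np.where(event, rng.poisson(1.5, n) + 1, 0)
    f["captures"] = counts.astype(float)
    f = cov.derive_covariates(f)
    specs = [cov.CovariateSpec("xcov", "xcov")]
    return HurdleModel(cov.build_design_matrix(f, specs))


class TestCaptureProbability:
    def test_symmetry_at_zero(self):
        p = _params([0.0], [0.0, 0.0])
        assert capture_probability(p, [1.0], 0) == 0.5

    def test_worked_example(self):
        # eta = -5 - 0.033*30 + 1.470*ln(4) = -3.952 -> p ~ 0.0189
        p = _params([-0.033, 1.470], [-5.0])
        got = capture_probability(p, [30.0, np.log(4.0)], 0)
        assert got == pytest.approx(0.0189, abs=5e-4)

    def test_monotone_decreasing_in_headline_depth(self):
        p = _params([-0.033], [-3.0])
        probs = [capture_probability(p, [d], 0) for d in (10, 50, 100, 200)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_row_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            capture_probability(_params([1.0], [0.0]), [1.0, 2.0], 0)


class TestZtpLogPmf:
    def test_normalization(self):
        n = np.arange(1, 201)
        assert np.exp(ztp_log_pmf(n, 2.1)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_lambda_limit_all_mass_at_one(self):
        assert np.exp(ztp_log_pmf(1, 1e-8)) == pytest.approx(1.0, abs=1e-6)

    def test_direct_formula_value(self):
        lam = 2.1
        expect = lam ** 2 * np.exp(-lam) / (2 * (1 - np.exp(-lam)))
        assert np.exp(ztp_log_pmf(2, lam)) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.3077, abs=5e-5)

    def test_zero_count_outside_support(self):
        with pytest.raises(ValueError):
            ztp_log_pmf(0, 2.0)


class TestLikelihoodAndPrior:
    def _model_from(self, events, counts, x=None):
        n = len(events)
        f = make_effort_frame(n)
        f["start_time"] = pd.to_datetime("2003-11-01 06:00") + \
            pd.to_timedelta(np.arange(n) * 7, unit="h")
        f.loc[n // 2:, "start_time"] += pd.DateOffset(years=1)
        f["end_time"] = f["start_time"] + pd.Timedelta("4h")
        f["xcov"] = x if x is not None else 0.0
        f["observed"] = True
        f["captures"] = np.asarray(counts, dtype=float)
        f = cov.derive_covariates(f)
        return HurdleModel(cov.build_design_matrix(
            f, [cov.CovariateSpec("xcov", "xcov")]))

    def test_single_non_event_at_half_probability(self):
        m = self._model_from([0, 0], [0, 0])
        p = _params([0.0], [0.0, 0.0])
        assert m.log_likelihood(p) == pytest.approx(2 * np.log(0.5))

    def test_adding_event_adds_bernoulli_and_ztp_terms(self):
        m0 = self._model_from([0, 0], [0, 0])
        m1 = self._model_from([0, 1], [0, 2])
        p = _params([0.0], [0.0, 0.0])
        increment = m1.log_likelihood(p) - m0.log_likelihood(p)
        assert increment == pytest.approx(ztp_log_pmf(2, 2.1), abs=1e-12)

    def test_likelihood_invariant_under_event_count_permutation(self):
        # the ZTP stage factorizes from the logistic stage
        m1 = self._model_from([1, 1, 0, 1], [3, 1, 0, 2])
        m2 = self._model_from([1, 1, 0, 1], [2, 3, 0, 1])
        p = _params([0.2], [-0.5, 0.1], lam=1.7)
        assert m1.log_likelihood(p) == pytest.approx(m2.log_likelihood(p))

    def test_event_with_zero_count_is_inconsistent(self):
        f = make_effort_frame(2)
        f["observed"] = True
        f["captures"] = [1.0, 0.0]
        f = cov.derive_covariates(f)
        f.loc[1, "fishing_year"] = f.loc[0, "fishing_year"] + 1  # two years
        d = cov.build_design_matrix(f, [])
        d.y[1] = 1.0  # claims an event but count is 0
        with pytest.raises(ValueError, match="count"):
            HurdleModel(d)

    def test_lambda_outside_uniform_support(self):
        m = self._model_from([0, 1], [0, 2])
        p = _params([0.0], [0.0, 0.0], lam=40.0)
        assert m.log_prior(p) == -np.inf

    def test_half_cauchy_density_at_its_scale(self):
        m = self._model_from([0, 1], [0, 2])
        base = _params([0.0], [0.0, 0.0], sigma=1.0)
        at_scale = _params([0.0], [0.0, 0.0], sigma=25.0)
        diff = m.log_prior(at_scale) - m.log_prior(base)
        from bycatch.hurdle import _half_cauchy_logpdf, _normal_logpdf
        expect = (_half_cauchy_logpdf(25.0, 25.0) - _half_cauchy_logpdf(1.0, 25.0)
                  + 2 * (_normal_logpdf(0, 0, 25.0) - _normal_logpdf(0, 0, 1.0)))
        assert diff == pytest.approx(expect, abs=1e-10)
        assert _half_cauchy_logpdf(25.0, 25.0) == pytest.approx(
            np.log(1.0 / (25.0 * np.pi)))

    def test_wider_beta_prior_is_flatter(self):
        m = self._model_from([0, 1], [0, 2])
        p = _params([5.0], [0.0, 0.0])
        narrow = m.log_prior(p)
        m.priors = PriorSpec(beta_sd=200.0)
        wide = m.log_prior(p)
        # a diffuse prior penalizes a fixed coefficient less steeply
        ref = _params([0.0], [0.0, 0.0])
        m.priors = PriorSpec(beta_sd=100.0)
        pen_narrow = m.log_prior(ref) - narrow
        m.priors = PriorSpec(beta_sd=200.0)
        pen_wide = m.log_prior(ref) - wide
        assert pen_wide < pen_narrow

    def test_posterior_is_likelihood_plus_prior_along_lines(self):
        m = self._model_from([0, 1, 1, 0], [0, 2, 1, 0],
                             x=np.array([0.5, -0.2, 1.0, 0.3]))
        rng = np.random.default_rng(8)
        base = m.initial_params()
        for _ in range(10):
            p1 = _params(base.beta + rng.normal(0, 0.5, 1),
                         base.alpha + rng.normal(0, 0.5, 2),
                         mu=rng.normal(), sigma=np.exp(rng.normal()),
                         lam=rng.uniform(0.6, 5.0))
            lhs = m.log_posterior(p1) - m.log_posterior(base)
            rhs = (m.log_likelihood(p1) - m.log_likelihood(base)
                   + m.log_prior(p1) - m.log_prior(base))
            assert lhs == pytest.approx(rhs, abs=1e-9)


class TestMcmcConfig:
    def test_default_schedule_keeps_5000_draws_per_chain(self):
        assert McmcConfig().draws_per_chain == 5000

    def test_thin_must_divide_iterations(self):
        with pytest.raises(ValueError):
            McmcConfig(n_iter=1000, thin=3)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            McmcConfig(n_chains=1)


class TestFit:
    def test_draw_counts_match_schedule(self):
        m = _toy_model()
        res = m.fit(McmcConfig(n_burn=200, n_iter=1000, thin=10, seed=1))
        assert res.posterior.chains.shape == (2, 100, len(m.param_names))

    def test_chains_converge_from_overdispersed_starts(self):
        m = _toy_model(n=300, seed=2)
        res = m.fit(McmcConfig(n_burn=2000, n_iter=8000, thin=10, seed=3))
        assert float(res.posterior.rhat().max()) < 1.05

    def test_posterior_matches_ml_on_large_logistic_data(self):
        # Bernstein-von Mises: diffuse priors, n large -> posterior ~ MLE
        import statsmodels.api as sm
        m = _toy_model(n=1500, seed=4, p_event=0.25)
        res = m.fit(McmcConfig(n_burn=1500, n_iter=6000, thin=10, seed=5))
        s = res.summary()
        X = sm.add_constant(m.design.X.to_numpy())
        ml = sm.GLM(m.design.y, X, family=sm.families.Binomial()).fit()
        post_mean = s.loc["xcov", "mean"]
        post_sd = s.loc["xcov", "sd"]
        assert abs(post_mean - ml.params[1]) < 2 * post_sd

    def test_posterior_round_trip_through_csv(self, tmp_path):
        m = _toy_model()
        res = m.fit(McmcConfig(n_burn=100, n_iter=400, thin=10, seed=6))
        p = tmp_path / "draws.csv"
        res.save(p, tmp_path / "diag.json")
        back = PosteriorSamples.from_frame(pd.read_csv(p))
        np.testing.assert_allclose(back.chains, res.posterior.chains, rtol=1e-12)
        assert back.param_names == res.posterior.param_names

    def test_fit_requires_an_event(self):
        f = make_effort_frame(10)
        f["observed"] = True
        f["captures"] = 0.0
        f = cov.derive_covariates(f)
        model = HurdleModel(cov.build_design_matrix(f, []))
        with pytest.raises(ValueError, match="event"):
            model.fit(McmcConfig(n_burn=10, n_iter=20, thin=2, seed=0))
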