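"""Prior/posterior evaluation, sampler determinism, conjugate check, TR summaries."""

import math

import numpy as np
import pytest

from bayesaft.data_model import CauseSpecificView
from bayesaft.bayes_engine import (
    MCMCConfig,
    PosteriorDraws,
    PriorSpec,
    log_posterior,
    log_prior,
    param_draws,
    run_mcmc,
    summarize,
)
from bayesaft.parametric_models import AFTParams, Family, censored_loglik

_LOG_2PI = math.log(2 * math.pi)


def _intercept_view(times, d):
    times = np.asarray(times, dtype=float)
    return CauseSpecificView(
        times=times,
        d=np.asarray(d),
        design=np.ones((times.size, 1)),
        cause=None,
        column_names=["intercept"],
    )


def _toy_draws(theta_matrix, names, family=Family.WEIBULL, n_chains=1, fix_ancillary=None):
    """Wrap an explicit draws matrix in a PosteriorDraws object."""
    theta = np.asarray(theta_matrix, dtype=float)
    chains = theta.reshape(n_chains, -1, theta.shape[1])
    r = chains.shape[1]
    cfg = MCMCConfig(
        n_chains=n_chains,
        n_iter=2 * r * n_chains // n_chains,
        n_burnin=r * n_chains // n_chains,
        seed=0,
        fix_ancillary=fix_ancillary,
    )
    return PosteriorDraws(
        chains=chains,
        parameter_names=names,
        family=family,
        config=cfg,
        acceptance_rate=np.full(n_chains, 0.3),
        rhat=np.ones(theta.shape[1]),
    )


class TestLogPrior:
    def test_normal_density_at_mean(self):
        params = AFTParams(Family.WEIBULL, [0.0], 1.0)
        got = log_prior(params, PriorSpec(10_000.0), include_ancillary=False)
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi * 10_000.0))

    def test_ancillary_at_one_adds_same_constant(self):
        params = AFTParams(Family.WEIBULL, [0.0], 1.0)  # log ancillary = 0
        got = log_prior(params, PriorSpec(10_000.0))
        assert got == pytest.approx(-math.log(2 * math.pi * 10_000.0))

    def test_symmetric_in_beta(self):
        prior = PriorSpec(50.0)
        a = log_prior(AFTParams(Family.LOGNORMAL, [1.7, -0.3], 2.0), prior)
        b = log_prior(AFTParams(Family.LOGNORMAL, [-1.7, 0.3], 2.0), prior)
        assert a == pytest.approx(b)

    def test_variance_difference_is_analytic(self):
        beta = 3.0
        params = AFTParams(Family.WEIBULL, [beta], 1.0)
        diff = log_prior(params, PriorSpec(1.0), include_ancillary=False) - log_prior(
            params, PriorSpec(10_000.0), include_ancillary=False
        )
        expected = (-0.5 * beta**2 / 1.0 - 0.5 * math.log(2 * math.pi)) - (
            -0.5 * beta**2 / 10_000.0 - 0.5 * math.log(2 * math.pi * 10_000.0)
        )
        assert diff == pytest.approx(expected)


class TestLogPosterior:
    def _fixture(self):
        rng = np.random.default_rng(1)
        times = rng.uniform(1.0, 30.0, 5)
        d = np.array([1, 0, 1, 0, 1])
        x = np.column_stack([np.ones(5), rng.normal(size=5)])
        return CauseSpecificView(times, d, x, None, ["intercept", "x1"])

    def test_equals_sum_of_components(self):
        view = self._fixture()
        prior = PriorSpec(100.0)
        params = AFTParams(Family.WEIBULL, [-1.0, 0.4], 1.3)
        assert log_posterior(params, view, prior) == pytest.approx(
            censored_loglik(params, view) + log_prior(params, prior)
        )

    def test_flat_prior_shifts_loglik_by_constant(self):
        view = self._fixture()
        prior = PriorSpec(1e12)
        offsets = []
        for b1 in np.linspace(-2, 2, 9):
            params = AFTParams(Family.WEIBULL, [-1.0, b1], 1.3)
            offsets.append(log_posterior(params, view, prior) - censored_loglik(params, view))
        assert np.ptp(offsets) < 1e-6

    def test_shrinkage_direction(self):
        # at fixed |beta| large relative to every grid variance, widening the
        # prior raises the (unnormalized) posterior
        view = self._fixture()
        params = AFTParams(Family.LOGNORMAL, [150.0, -120.0], 1.0)
        lp = [
            log_posterior(params, view, PriorSpec(v)) for v in (1.0, 10.0, 100.0, 10_000.0)
        ]
        assert all(a < b for a, b in zip(lp, lp[1:]))


class TestSampler:
    def test_same_seed_gives_identical_draws(self, tiny_hf_view):
        cfg = MCMCConfig(n_chains=2, n_iter=600, n_burnin=300, seed=44)
        d1 = run_mcmc(tiny_hf_view, Family.WEIBULL, PriorSpec(), cfg)
        d2 = run_mcmc(tiny_hf_view, Family.WEIBULL, PriorSpec(), cfg)
        assert d1.draws.tobytes() == d2.draws.tobytes()
        assert np.array_equal(d1.acceptance_rate, d2.acceptance_rate)

    def test_different_seed_gives_different_draws(self, tiny_hf_view):
        d1 = run_mcmc(tiny_hf_view, Family.WEIBULL, PriorSpec(),
                      MCMCConfig(n_chains=1, n_iter=600, n_burnin=300, seed=1))
        d2 = run_mcmc(tiny_hf_view, Family.WEIBULL, PriorSpec(),
                      MCMCConfig(n_chains=1, n_iter=600, n_burnin=300, seed=2))
        assert d1.draws.tobytes() != d2.draws.tobytes()

    def test_retained_row_count_contract(self, tiny_hf_view):
        cfg = MCMCConfig(n_chains=2, n_iter=1000, n_burnin=400, thin=3, seed=5)
        draws = run_mcmc(tiny_hf_view, Family.WEIBULL, PriorSpec(), cfg)
        assert draws.n_retained == 2 * ((1000 - 400) // 3)

    def test_exponential_posterior_matches_conjugate_gamma(self):
        """Intercept-only Weibull with shape pinned at 1 under a flat prior:
        the rate posterior is Gamma(#events, total time) up to the prior."""
        rng = np.random.default_rng(5)
        n = 200
        latent = rng.exponential(20.0, n)
        times = np.minimum(latent, 30.0)
        d = (latent <= 30.0).astype(int)
        view = _intercept_view(times, d)
        draws = run_mcmc(
            view,
            Family.WEIBULL,
            PriorSpec(1e12),
            MCMCConfig(n_chains=2, n_iter=6000, n_burnin=3000, seed=7, fix_ancillary=1.0),
        )
        lam = np.exp(draws.draws[:, 0])
        gamma_mean = d.sum() / times.sum()
        assert lam.mean() == pytest.approx(gamma_mean, rel=0.03)

    def test_acceptance_rate_lands_near_target(self, n800_hf_view):
        draws = run_mcmc(
            n800_hf_view,
            Family.WEIBULL,
            PriorSpec(),
            MCMCConfig(n_chains=2, n_iter=3000, n_burnin=1500, seed=21),
        )
        assert np.all(draws.acceptance_rate >= 0.15)
        assert np.all(draws.acceptance_rate <= 0.5)

    def test_zero_events_rejected(self):
        view = _intercept_view([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError, match="no events"):
            run_mcmc(view, Family.WEIBULL, PriorSpec(), MCMCConfig(n_iter=100, n_burnin=50))


class TestSummarize:
    def test_null_coefficient_gives_unit_ratio(self):
        theta = np.column_stack([np.zeros(100), np.zeros(100), np.zeros(100)])
        draws = _toy_draws(theta, ["intercept", "x1", "log_shape"])
        summ = summarize(draws)
        tr = summ.ratio("x1")
        assert (tr.tr, tr.ci_low, tr.ci_high, tr.significant) == (1.0, 1.0, 1.0, False)

    def test_interval_excluding_one_is_significant(self):
        rng = np.random.default_rng(0)
        # beta draws concentrated well below 0 on the log-normal scale -> TR < 1
        beta = rng.normal(-0.9, 0.35, 4000)
        theta = np.column_stack([np.zeros(4000), beta, np.zeros(4000)])
        draws = _toy_draws(theta, ["intercept", "x1", "log_spread"], family=Family.LOGNORMAL)
        tr = summarize(draws).ratio("x1")
        lo, hi = np.percentile(np.exp(beta), [2.5, 97.5])
        assert tr.ci_low == pytest.approx(lo)
        assert tr.ci_high == pytest.approx(hi)
        assert tr.significant == (not lo <= 1.0 <= hi)
        assert tr.significant  # interval like (0.2, 0.8) excludes 1

    def test_interval_straddling_one_not_significant(self):
        rng = np.random.default_rng(1)
        beta = rng.normal(-0.1, 0.3, 4000)
        theta = np.column_stack([np.zeros(4000), beta, np.zeros(4000)])
        draws = _toy_draws(theta, ["intercept", "x1", "log_spread"], family=Family.LOGNORMAL)
        tr = summarize(draws).ratio("x1")
        assert tr.ci_low < 1.0 < tr.ci_high
        assert not tr.significant

    def test_chain_merge_invariance(self, tiny_hf_view):
        cfg = MCMCConfig(n_chains=3, n_iter=800, n_burnin=400, seed=9)
        draws = run_mcmc(tiny_hf_view, Family.WEIBULL, PriorSpec(), cfg)
        merged = _toy_draws(
            np.concatenate([draws.chains[c] for c in range(3)], axis=0),
            draws.parameter_names,
        )
        s_orig = summarize(draws)
        s_merged = summarize(merged)
        for a, b in zip(s_orig.time_ratios, s_merged.time_ratios):
            assert a.tr == pytest.approx(b.tr)
            assert a.ci_low == pytest.approx(b.ci_low)
            assert a.ci_high == pytest.approx(b.ci_high)

    def test_every_noninterceptcolumn_summarized_once(self, n800_hf_view):
        draws = run_mcmc(
            n800_hf_view, Family.WEIBULL, PriorSpec(),
            MCMCConfig(n_chains=1, n_iter=800, n_burnin=400, seed=2),
        )
        summ = summarize(draws)
        assert [tr.name for tr in summ.time_ratios] == ["x1", "x2", "x3"]

    def test_param_draws_with_fixed_ancillary(self):
        theta = np.array([[0.0, 1.0], [0.5, -1.0]])
        draws = _toy_draws(theta, ["intercept", "x1"], fix_ancillary=2.0)
        beta, anc = param_draws(draws)
        assert beta.shape == (2, 2)
        np.testing.assert_array_equal(anc, [2.0, 2.0])
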