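"""Diffuse-normal priors, posterior evaluation, seeded MCMC and TR summaries.

Priors
------
Each regression coefficient gets an independent Normal(0, v) prior with a
large default variance v = 10,000 (effectively non-informative on the
coefficient scale).  The positive ancillary parameter (Weibull/log-logistic
shape p, or log-normal spread delta) is sampled on the log scale with the
same Normal(0, v) prior on log(ancillary).

Sampler
-------
Adaptive random-walk Metropolis with a joint Gaussian proposal on
theta = (beta, log ancillary).  During burn-in the proposal covariance is
adapted toward the running posterior covariance and the global step size is
tuned toward the classic 0.234 acceptance target by a Robbins-Monro
recursion; after burn-in all adaptation is frozen so the retained chain is a
genuine Markov chain.  Chains are initialized at the maximum-likelihood
point found by a short numerical optimization (falling back to zeros), and
all randomness flows from a single integer seed, so identical seed + config
reproduce the draws bit for bit.

Summaries report each non-intercept coefficient on the time-ratio scale:
the coefficient of every retained draw is converted with that draw's
ancillary value, and the posterior median and equal-tailed 2.5-97.5
percentile interval of the converted draws are reported.  A covariate is
flagged "significant" when the 95% credible interval excludes TR = 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .data_model import Cause, CauseSpecificView
from .parametric_models import AFTParams, Family, TimeRatio, censored_loglik

__all__ = [
    "PriorSpec",
    "MCMCConfig",
    "PosteriorDraws",
    "FitSummary",
    "log_prior",
    "log_posterior",
    "find_mle",
    "run_mcmc",
    "param_draws",
    "summarize",
    "export_draws",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorSpec:
    """Independent Normal(0, beta_variance) priors on coefficients and log ancillary."""

    beta_variance: float = 10_000.0

    def __post_init__(self):
        if not (self.beta_variance > 0):
            raise ValueError("prior variance must be positive")


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``fix_ancillary`` pins the ancillary parameter at a constant instead of
    sampling it (e.g. shape 1 turns the Weibull family into the exponential
    model).  ``init`` optionally supplies a starting theta vector on the
    sampling scale (beta, log ancillary); by default chains start at the
    MLE.
    """

    n_chains: int = 2
    n_iter: int = 20_000
    n_burnin: int = 10_000
    thin: int = 1
    seed: int = 0
    init: tuple = None
    fix_ancillary: float = None
    target_accept: float = 0.234

    def __post_init__(self):
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")
        if self.fix_ancillary is not None and not self.fix_ancillary > 0:
            raise ValueError("fix_ancillary must be positive")


@dataclass
class PosteriorDraws:
    """Retained MCMC output.

    ``chains`` has shape (n_chains, retained_per_chain, dim) on the sampling
    scale (beta columns then, unless the ancillary was fixed, log ancillary).
    ``draws`` is the chain-stacked (rows, dim) matrix.
    """

    chains: np.ndarray
    parameter_names: list
    family: Family
    config: MCMCConfig
    acceptance_rate: np.ndarray
    rhat: np.ndarray

    @property
    def draws(self) -> np.ndarray:
        return self.chains.reshape(-1, self.chains.shape[2])

    @property
    def n_retained(self) -> int:
        return self.chains.shape[0] * self.chains.shape[1]

    @property
    def has_free_ancillary(self) -> bool:
        return self.config.fix_ancillary is None

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for c in range(self.chains.shape[0]):
            df = pd.DataFrame(self.chains[c], columns=self.parameter_names)
            df.insert(0, "iteration", np.arange(self.chains.shape[1]))
            df.insert(0, "chain", c)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


@dataclass
class FitSummary:
    """Per-covariate time ratios for one cause-specific fit (a results-table row set)."""

    cause: Cause
    family: Family
    time_ratios: list
    ancillary_median: float
    rhat_max: float
    acceptance_rate: np.ndarray

    def ratio(self, name: str) -> TimeRatio:
        for tr in self.time_ratios:
            if tr.name == name:
                return tr
        raise KeyError(name)

    @property
    def significant_columns(self) -> list:
        return [tr.name for tr in self.time_ratios if tr.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "covariate": tr.name,
                    "time_ratio": tr.tr,
                    "ci_low": tr.ci_low,
                    "ci_high": tr.ci_high,
                    "significant": tr.significant,
                }
                for tr in self.time_ratios
            ]
        )


def log_prior(params: AFTParams, prior: PriorSpec, include_ancillary: bool = True) -> float:
    """Sum of Normal(0, v) log densities over beta and (optionally) log ancillary."""
    v = prior.beta_variance
    k = params.beta.shape[0]
    lp = -0.5 * float(np.sum(params.beta**2)) / v - 0.5 * k * (_LOG_2PI + math.log(v))
    if include_ancillary:
        la = math.log(params.ancillary)
        lp += -0.5 * la * la / v - 0.5 * (_LOG_2PI + math.log(v))
    return lp


def log_posterior(params: AFTParams, view: CauseSpecificView, prior: PriorSpec) -> float:
    """Unnormalized log posterior: censored log-likelihood + log prior."""
    return censored_loglik(params, view) + log_prior(params, prior)


def _make_log_post(view, family, prior, fix_ancillary):
    """Closure evaluating the unnormalized log posterior on the sampling scale."""
    X = view.design
    t = view.times
    logt = np.log(t)
    d = view.d.astype(bool)
    nd = ~d
    p_cols = X.shape[1]
    v = prior.beta_variance
    sq = math.sqrt
    family = Family(family)

    def log_post(theta):
        beta = theta[:p_cols]
        if fix_ancillary is None:
            log_anc = theta[p_cols]
            if abs(log_anc) > 50.0:  # guard exp over/underflow
                return -np.inf
            a = math.exp(log_anc)
        else:
            log_anc = 0.0
            a = fix_ancillary
        eta = X @ beta
        with np.errstate(over="ignore", invalid="ignore"):
            if family is Family.WEIBULL:
                z = eta + a * logt
                ll = float(
                    np.sum(eta[d] + math.log(a) + (a - 1.0) * logt[d]) - np.sum(np.exp(z))
                )
            elif family is Family.LOGLOGISTIC:
                z = eta + a * logt
                sp = np.logaddexp(0.0, z)
                ll = float(
                    np.sum(eta[d] + math.log(a) + (a - 1.0) * logt[d] - sp[d])
                    - np.sum(sp)
                )
            else:
                s = sq(a)
                zz = (logt - eta) / s
                ll = float(
                    np.sum(
                        -logt[d] - 0.5 * math.log(2.0 * math.pi * a) - 0.5 * zz[d] ** 2
                    )
                    + np.sum(_norm_logsf(zz[nd]))
                )
        if not np.isfinite(ll):
            return -np.inf
        lp = -0.5 * float(beta @ beta) / v
        if fix_ancillary is None:
            lp += -0.5 * log_anc * log_anc / v
        return ll + lp

    return log_post, p_cols


def _norm_logsf(z):
    # scipy's norm.logsf is accurate but slow through the distribution
    # machinery; call the underlying special function directly.
    from scipy.special import log_ndtr

    return log_ndtr(-np.asarray(z, dtype=float))


def find_mle(view: CauseSpecificView, family: Family, fix_ancillary: float = None):
    """Numerical maximum-likelihood point on the sampling scale (beta, log ancillary).

    Returns the optimizer's best theta; used for chain initialization and as
    a convenience for flat-prior cross-checks.
    """
    flat = PriorSpec(beta_variance=1e300)  # prior contribution ~ 0
    log_post, p_cols = _make_log_post(view, family, flat, fix_ancillary)
    dim = p_cols + (1 if fix_ancillary is None else 0)

    def neg(theta):
        lp = log_post(theta)
        return 1e10 if not np.isfinite(lp) else -lp

    x0 = np.zeros(dim)
    best = None
    for start in (x0,):
        res = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8})
        res2 = optimize.minimize(neg, res.x, method="BFGS",
                                 options={"maxiter": 500})
        cand = res2 if res2.fun <= res.fun else res
        if best is None or cand.fun < best.fun:
            best = cand
    if not np.isfinite(best.fun) or best.fun >= 1e10:
        return np.zeros(dim)
    return np.asarray(best.x, dtype=float)


def run_mcmc(
    view: CauseSpecificView,
    family: Family,
    prior: PriorSpec = None,
    config: MCMCConfig = None,
) -> PosteriorDraws:
    """Sample the posterior of (beta, log ancillary) by adaptive random-walk Metropolis.

    Adaptation (proposal covariance + step size toward the 0.234 acceptance
    target) runs during burn-in only.  Emits a warning, not an error, if any
    split-Rhat exceeds 1.1.
    """
    prior = prior or PriorSpec()
    config = config or MCMCConfig()
    family = Family(family)
    if view.n_events == 0:
        raise ValueError("no events for this cause: likelihood is degenerate")
    log_post, p_cols = _make_log_post(view, family, prior, config.fix_ancillary)
    dim = p_cols + (1 if config.fix_ancillary is None else 0)

    if config.init is not None:
        init = np.asarray(config.init, dtype=float)
        if init.shape != (dim,):
            raise ValueError(f"init must have {dim} entries")
    else:
        init = find_mle(view, family, config.fix_ancillary)
    if not np.isfinite(log_post(init)):
        raise ValueError(
            "log posterior is non-finite at the initial point; "
            "consider rescaling covariates"
        )

    retained = (config.n_iter - config.n_burnin) // config.thin
    chains = np.empty((config.n_chains, retained, dim))
    acc_rates = np.empty(config.n_chains)
    chain_seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)

    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        theta = init.copy()
        lp = log_post(theta)
        scale = 2.38 / math.sqrt(dim)
        L = np.eye(dim)
        mean = np.zeros(dim)
        m2 = np.zeros((dim, dim))
        n_seen = 0
        kept = 0
        accepted_post = 0
        for it in range(config.n_iter):
            prop = theta + scale * (L @ rng.standard_normal(dim))
            lpp = log_post(prop)
            log_u = math.log(rng.random())
            alpha = min(1.0, math.exp(min(0.0, lpp - lp))) if np.isfinite(lpp) else 0.0
            if log_u < lpp - lp:
                theta = prop
                lp = lpp
                if it >= config.n_burnin:
                    accepted_post += 1
            if it < config.n_burnin:
                # Robbins-Monro step-size tuning toward the acceptance target
                gamma = (it + 1) ** -0.6
                scale *= math.exp(gamma * (alpha - config.target_accept))
                # running covariance (Welford), refreshed Cholesky every 200 its
                n_seen += 1
                delta = theta - mean
                mean += delta / n_seen
                m2 += np.outer(delta, theta - mean)
                if n_seen > 2 * dim and it % 200 == 199:
                    cov = m2 / (n_seen - 1) + 1e-9 * np.eye(dim)
                    try:
                        L = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass
            else:
                if (it - config.n_burnin) % config.thin == 0 and kept < retained:
                    chains[c, kept] = theta
                    kept += 1
        acc_rates[c] = accepted_post / (config.n_iter - config.n_burnin)

    rhat = _split_rhat(chains)
    if np.any(rhat > 1.1):
        worst = int(np.nanargmax(rhat))
        warnings.warn(
            f"possible non-convergence: split-Rhat up to {rhat[worst]:.3f} "
            f"(parameter index {worst}); consider longer chains",
            RuntimeWarning,
        )

    names = list(view.column_names)
    if config.fix_ancillary is None:
        names.append("log_spread" if family is Family.LOGNORMAL else "log_shape")
    return PosteriorDraws(
        chains=chains,
        parameter_names=names,
        family=family,
        config=config,
        acceptance_rate=acc_rates,
        rhat=rhat,
    )


def _split_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-Rhat per parameter (each chain halved, rank-free classic form)."""
    c, r, dim = chains.shape
    half = r // 2
    if half < 2:
        return np.full(dim, np.nan)
    segs = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = segs.shape[0], half
    out = np.empty(dim)
    for j in range(dim):
        x = segs[:, :, j]
        means = x.mean(axis=1)
        w = x.var(axis=1, ddof=1).mean()
        b = n * means.var(ddof=1)
        if w <= 0:
            out[j] = 1.0
            continue
        var_plus = (n - 1) / n * w + b / n
        out[j] = math.sqrt(var_plus / w)
    return out


def param_draws(draws: PosteriorDraws):
    """Split retained draws into (beta matrix, ancillary vector) on the natural scale."""
    mat = draws.draws
    if draws.has_free_ancillary:
        return mat[:, :-1], np.exp(mat[:, -1])
    anc = float(draws.config.fix_ancillary)
    return mat, np.full(mat.shape[0], anc)


def _tr_draws_for_column(family: Family, beta_col: np.ndarray, anc: np.ndarray):
    if family is Family.LOGNORMAL:
        return np.exp(beta_col)
    return np.exp(-beta_col / anc)


def summarize(draws: PosteriorDraws, cause: Cause = None, level: float = 0.95) -> FitSummary:
    """Posterior medians and equal-tailed credible intervals on the TR scale.

    Every non-intercept design column is summarized exactly once; the
    coefficient -> TR conversion uses each draw's own ancillary value.
    """
    if draws.n_retained == 0:
        raise ValueError("no retained draws")
    beta, anc = param_draws(draws)
    lo_q, hi_q = 50 * (1 - level), 100 - 50 * (1 - level)
    ratios = []
    n_beta = beta.shape[1]
    for j in range(1, n_beta):  # skip intercept
        tr = _tr_draws_for_column(draws.family, beta[:, j], anc)
        med = float(np.median(tr))
        lo, hi = (float(q) for q in np.percentile(tr, [lo_q, hi_q]))
        ratios.append(
            TimeRatio(
                name=draws.parameter_names[j],
                tr=med,
                ci_low=lo,
                ci_high=hi,
                significant=not (lo <= 1.0 <= hi),
            )
        )
    return FitSummary(
        cause=cause,
        family=draws.family,
        time_ratios=ratios,
        ancillary_median=float(np.median(anc)),
        rhat_max=float(np.nanmax(draws.rhat)) if draws.rhat.size else float("nan"),
        acceptance_rate=draws.acceptance_rate,
    )


def export_draws(draws: PosteriorDraws, path, sep: str = ",") -> None:
    """Write retained draws as delimited text (chain, iteration, parameters)."""
    draws.to_frame().to_csv(path, sep=sep, index=False)
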