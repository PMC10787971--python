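"""Weibull, log-logistic and log-normal AFT families for right-censored data.

All three families are driven by the linear predictor ``x · beta`` (design
row times coefficient vector, intercept included).  The Weibull and
log-logistic families use the rate parameterization

    lambda = exp(x · beta),    shape p > 0,

with

    Weibull:       f(t) = lambda p t^(p-1) exp(-lambda t^p),
                   S(t) = exp(-lambda t^p)
    log-logistic:  S(t) = 1 / (1 + lambda t^p),
                   f(t) = lambda p t^(p-1) / (1 + lambda t^p)^2

while the log-normal family places the linear predictor on the log-time
location scale,

    log T ~ Normal(mu = x · beta, delta),
    S(t) = 1 - Phi((ln t - mu) / sqrt(delta)),

with spread parameter delta > 0 (the variance of log time).

Under this convention a positive Weibull/log-logistic coefficient *shortens*
survival.  Reporting happens on the time-ratio (TR) scale: the multiplicative
effect of a one-unit covariate increase on survival time,

    TR_j = exp(-beta_j / p)   (Weibull, log-logistic)
    TR_j = exp(beta_j)        (log-normal)

so TR < 1 always means shorter survival, whichever family is in play.

The censored log-likelihood is

    sum_i [ d_i log f(t_i) + (1 - d_i) log S(t_i) ]

with d_i = 1 for an event of the modelled cause and d_i = 0 otherwise
(censoring or a competing-cause death).  Everything is computed in log space
(log1p / logaddexp / logsf) so large lambda * t^p does not overflow.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "Family",
    "AFTParams",
    "TimeRatio",
    "log_f",
    "log_S",
    "censored_loglik",
    "to_time_ratio",
    "median_survival_time",
]


class Family(enum.Enum):
    # order fixed: used as the deterministic tie-break in model ranking
    WEIBULL = "weibull"
    LOGNORMAL = "lognormal"
    LOGLOGISTIC = "loglogistic"


@dataclass
class AFTParams:
    """Coefficients plus ancillary parameter for one AFT family.

    ``beta`` is ordered like the design columns (intercept first).
    ``ancillary`` is the shape p for WEIBULL/LOGLOGISTIC and the log-time
    variance delta for LOGNORMAL; it must be positive.
    """

    family: Family
    beta: np.ndarray
    ancillary: float

    def __post_init__(self):
        self.family = Family(self.family)
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if not (np.isfinite(self.ancillary) and self.ancillary > 0):
            raise ValueError(f"ancillary parameter must be positive, got {self.ancillary}")


@dataclass
class TimeRatio:
    """Posterior time-ratio summary for one design column.

    ``significant`` is True iff the 95% equal-tailed credible interval
    excludes TR = 1.
    """

    name: str
    tr: float
    ci_low: float
    ci_high: float
    significant: bool

    def __post_init__(self):
        if not (self.ci_low <= self.tr <= self.ci_high):
            raise ValueError(
                f"{self.name}: point estimate {self.tr} outside interval "
                f"({self.ci_low}, {self.ci_high})"
            )


def _eta(params: AFTParams, x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x @ params.beta


def log_f(params: AFTParams, x, t):
    """Log density of the event time at ``t`` for covariate row(s) ``x``.

    ``x`` may be a single design row or an (n, p) matrix; ``t`` a scalar or
    matching vector of positive times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("event times must be positive")
    eta = _eta(params, x)
    logt = np.log(t)
    a = params.ancillary
    if params.family is Family.WEIBULL:
        z = eta + a * logt
        with np.errstate(over="ignore"):
            return eta + np.log(a) + (a - 1.0) * logt - np.exp(z)
    if params.family is Family.LOGLOGISTIC:
        z = eta + a * logt
        return eta + np.log(a) + (a - 1.0) * logt - 2.0 * np.logaddexp(0.0, z)
    # log-normal: eta is the location of log T, a the variance of log T
    zz = (logt - eta) / np.sqrt(a)
    return -logt - 0.5 * np.log(2.0 * np.pi * a) - 0.5 * zz**2


def log_S(params: AFTParams, x, t):
    """Log survival probability at ``t``; tends to 0 as t -> 0+."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("times must be positive")
    eta = _eta(params, x)
    logt = np.log(t)
    a = params.ancillary
    if params.family is Family.WEIBULL:
        with np.errstate(over="ignore"):
            return -np.exp(eta + a * logt)
    if params.family is Family.LOGLOGISTIC:
        return -np.logaddexp(0.0, eta + a * logt)
    zz = (logt - eta) / np.sqrt(a)
    return norm.logsf(zz)


def censored_loglik(params: AFTParams, view) -> float:
    """Right-censored log-likelihood over a cause-specific view.

    ``sum_i d_i log f(t_i) + (1 - d_i) log S(t_i)``.  Raises if any
    subject's contribution is non-finite (e.g. a density that underflowed to
    exactly zero at an event time), naming the offending subject index.
    """
    if params.beta.shape[0] != view.design.shape[1]:
        raise ValueError(
            f"beta has {params.beta.shape[0]} entries for "
            f"{view.design.shape[1]} design columns"
        )
    d = view.d.astype(bool)
    contrib = np.empty(view.n, dtype=float)
    if d.any():
        contrib[d] = log_f(params, view.design[d], view.times[d])
    if (~d).any():
        contrib[~d] = log_S(params, view.design[~d], view.times[~d])
    bad = ~np.isfinite(contrib)
    if bad.any():
        raise FloatingPointError(
            f"non-finite log-likelihood contribution at subject index "
            f"{int(np.flatnonzero(bad)[0])}"
        )
    return float(contrib.sum())


def to_time_ratio(family: Family, beta_j: float, ancillary: float = None) -> float:
    """Convert one regression coefficient to the time-ratio scale.

    Weibull/log-logistic rate coefficients convert as exp(-beta_j / p);
    the log-normal location is already log time, so TR = exp(beta_j).
    """
    family = Family(family)
    if family is Family.LOGNORMAL:
        return float(np.exp(beta_j))
    if ancillary is None or ancillary <= 0:
        raise ValueError("shape p must be positive for Weibull/log-logistic")
    return float(np.exp(-beta_j / ancillary))


def median_survival_time(params: AFTParams, x) -> float:
    """Closed-form median survival time for one covariate row."""
    eta = float(_eta(params, x))
    a = params.ancillary
    if params.family is Family.WEIBULL:
        return float((np.log(2.0) * np.exp(-eta)) ** (1.0 / a))
    if params.family is Family.LOGLOGISTIC:
        return float(np.exp(-eta / a))
    return float(np.exp(eta))
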