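"""Descriptive survival layer: person-time rates, Kaplan-Meier, log-rank.

All quantities here are *cause-specific*: competing-cause deaths are treated
as censored, matching the d-coding of the modeling layer.  The estimates
should therefore be read as cause-specific survival/rate summaries, not as
marginal cumulative-incidence quantities.

Conventions
-----------
* Person-time is measured in person-months; rates are reported per 1000
  person-months with exact Poisson (chi-square quantile) 95% confidence
  limits on the event count.
* Kaplan-Meier uses the product-limit estimator with Greenwood variance;
  intervals are reported on the plain probability scale (truncated to
  [0, 1]); a complementary log-log transform is available but off by
  default.  At tied death/censoring times the death takes precedence
  (censored subjects remain in the risk set for that instant).
* The log-rank test is the standard observed-minus-expected chi-square over
  pooled event times; an ordered-scores trend variant is available for
  ordinal groupings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Cause, CauseSpecificView, Cohort, CovariateKind, Event

__all__ = [
    "RateEstimate",
    "KMEstimate",
    "LogRankResult",
    "person_time_rate",
    "km_curve",
    "log_rank",
    "cohort_summary",
    "rate_table",
]


@dataclass
class RateEstimate:
    """Cause-specific failures over person-time, per 1000 person-months."""

    failures: int
    person_time: float
    rate_per_1000: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.rate_per_1000 <= self.ci_high):
            raise ValueError("rate outside its confidence interval")


@dataclass
class KMEstimate:
    """Product-limit survival curve with Greenwood variance and 95% CIs."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value: S at the largest event time <= t (1.0 before the first)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def ci_at(self, t: float):
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        return float(self.ci_low[idx]), float(self.ci_high[idx])


@dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float
    group_labels: list

    def __post_init__(self):
        if self.chi_square < 0:
            raise ValueError("chi-square must be nonnegative")


def person_time_rate(
    times, d, mask=None, level: float = 0.95
) -> RateEstimate:
    """Failures / person-time in a stratum, with exact Poisson 95% CI.

    ``times`` in months, ``d`` the cause-specific 0/1 indicator, ``mask`` an
    optional boolean subject subset.  The confidence limits are the
    chi-square-quantile (Garwood) limits on the count, scaled by
    person-time.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(d, dtype=int)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty stratum")
        times, d = times[mask], d[mask]
    pt = float(times.sum())
    if pt <= 0:
        raise ValueError("person-time must be positive")
    k = int(d.sum())
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2, 2 * k) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2.0
    scale = 1000.0 / pt
    return RateEstimate(
        failures=k,
        person_time=pt,
        rate_per_1000=k * scale,
        ci_low=lo * scale,
        ci_high=hi * scale,
    )


def km_curve(times, d, mask=None, level: float = 0.95, transform: str = "plain") -> KMEstimate:
    """Kaplan-Meier product-limit estimate with Greenwood variance.

    ``transform='plain'`` gives symmetric normal intervals on the
    probability scale truncated to [0, 1]; ``transform='loglog'`` uses the
    complementary log-log transform.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(d, dtype=int)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        times, d = times[mask], d[mask]
    if times.size == 0:
        raise ValueError("need at least one subject")
    event_times = np.unique(times[d == 1])
    surv = np.empty(event_times.size)
    var = np.empty(event_times.size)
    s = 1.0
    gw = 0.0  # Greenwood cumulative sum
    for i, tau in enumerate(event_times):
        n_at_risk = int(np.sum(times >= tau))
        n_events = int(np.sum((times == tau) & (d == 1)))
        s *= 1.0 - n_events / n_at_risk
        if n_at_risk > n_events:
            gw += n_events / (n_at_risk * (n_at_risk - n_events))
        else:
            gw = np.inf
        surv[i] = s
        var[i] = s * s * gw if np.isfinite(gw) else 0.0
    z = stats.norm.ppf(0.5 + level / 2)
    se = np.sqrt(var)
    if transform == "loglog":
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where((surv > 0) & (surv < 1), np.log(-np.log(surv)), np.nan)
            se_theta = np.where(
                (surv > 0) & (surv < 1), se / np.abs(surv * np.log(surv)), np.nan
            )
            lo = np.where(np.isnan(theta), surv, np.exp(-np.exp(theta + z * se_theta)))
            hi = np.where(np.isnan(theta), surv, np.exp(-np.exp(theta - z * se_theta)))
    else:
        lo = np.clip(surv - z * se, 0.0, 1.0)
        hi = np.clip(surv + z * se, 0.0, 1.0)
    return KMEstimate(times=event_times, survival=surv, variance=var, ci_low=lo, ci_high=hi)


def log_rank(times, d, groups, trend_scores: dict = None) -> LogRankResult:
    """Log-rank comparison of cause-specific survival across groups.

    With ``trend_scores`` (a mapping group label -> numeric score) the
    1-degree-of-freedom trend statistic ``U^2 / Var(U)`` with
    ``U = sum_g s_g (O_g - E_g)`` is used instead of the (k-1)-df statistic.
    """
    times = np.asarray(times, dtype=float)
    d = np.asarray(d, dtype=int)
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups)]
    k = len(labels)
    if k < 2:
        raise ValueError("need at least two nonempty groups")
    g_idx = np.array([labels.index(g) for g in groups])
    event_times = np.unique(times[d == 1])
    o_minus_e = np.zeros(k)
    cov = np.zeros((k, k))
    for tau in event_times:
        at_risk = times >= tau
        n_j = int(at_risk.sum())
        d_j = int(np.sum((times == tau) & (d == 1)))
        if n_j == 0 or d_j == 0:
            continue
        n_gj = np.bincount(g_idx[at_risk], minlength=k).astype(float)
        d_gj = np.bincount(
            g_idx[(times == tau) & (d == 1)], minlength=k
        ).astype(float)
        e_gj = d_j * n_gj / n_j
        o_minus_e += d_gj - e_gj
        if n_j > 1:
            frac = n_gj / n_j
            factor = d_j * (n_j - d_j) / (n_j - 1)
            cov += factor * (np.diag(frac) - np.outer(frac, frac))
    if trend_scores is not None:
        s = np.array([float(trend_scores[lab]) for lab in labels])
        u = float(s @ o_minus_e)
        var_u = float(s @ cov @ s)
        chi2 = 0.0 if var_u <= 0 else u * u / var_u
        df = 1
    else:
        v = cov[: k - 1, : k - 1]
        o = o_minus_e[: k - 1]
        if np.allclose(v, 0):
            chi2 = 0.0
        else:
            chi2 = float(o @ np.linalg.pinv(v) @ o)
        chi2 = max(chi2, 0.0)
        df = k - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return LogRankResult(chi_square=chi2, df=df, p_value=p, group_labels=labels)


def cohort_summary(cohort: Cohort) -> pd.DataFrame:
    """Cohort bookkeeping: outcome counts and covariate level counts with percentages.

    Percentages are of the total cohort size, rounded to one decimal (the
    convention of registry descriptive tables).
    """
    n = len(cohort)
    counts = cohort.event_counts()
    rows = [
        {"characteristic": "total", "count": n, "percent": 100.0},
        _summary_row("hf_death", counts[Event.HF_DEATH], n),
        _summary_row("non_hf_death", counts[Event.NON_HF_DEATH], n),
        _summary_row("censored", counts[Event.CENSORED], n),
    ]
    for spec in cohort.specs:
        if spec.kind is CovariateKind.CONTINUOUS:
            vals = np.array(
                [float(r.covariates[spec.name]) for r in cohort.records], dtype=float
            )
            rows.append(
                {
                    "characteristic": f"{spec.name} (mean)",
                    "count": n,
                    "percent": round(float(vals.mean()), 1),
                }
            )
            continue
        levels = spec.levels if spec.kind is not CovariateKind.BINARY else [spec.levels[1]]
        for lvl in levels:
            c = sum(
                1 for r in cohort.records if str(r.covariates[spec.name]) == str(lvl)
            )
            rows.append(_summary_row(f"{spec.name}={lvl}", c, n))
    return pd.DataFrame(rows, columns=["characteristic", "count", "percent"])


def _summary_row(name: str, count: int, n: int) -> dict:
    return {"characteristic": name, "count": count, "percent": round(100.0 * count / n, 1)}


def rate_table(cohort: Cohort, cause: Cause) -> pd.DataFrame:
    """Per-covariate-level failures, person-time, rates and log-rank p-values.

    One row per level of each non-continuous covariate; continuous
    covariates get a trend log-rank over quartile bands.
    """
    from .data_model import cause_specific_view

    view = cause_specific_view(cohort, cause, check_rank=False)
    times, d = view.times, view.d
    rows = []
    for spec in cohort.specs:
        raw = [r.covariates[spec.name] for r in cohort.records]
        if spec.kind is CovariateKind.CONTINUOUS:
            vals = np.asarray(raw, dtype=float)
            qs = np.quantile(vals, [0.25, 0.5, 0.75])
            bands = np.searchsorted(qs, vals, side="right")
            res = log_rank(times, d, bands, trend_scores={i: i for i in range(4)})
            rows.append(
                {
                    "covariate": spec.name,
                    "level": "(trend)",
                    "failures": int(d.sum()),
                    "person_time": float(times.sum()),
                    "rate_per_1000": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "logrank_p": res.p_value,
                }
            )
            continue
        groups = np.array([str(v) for v in raw])
        if spec.kind is CovariateKind.ORDINAL_TREND:
            scores = {str(lvl): i for i, lvl in enumerate(spec.levels)}
            present = [g for g in scores if (groups == g).any()]
            res = (
                log_rank(times, d, groups, trend_scores=scores)
                if len(present) > 1
                else None
            )
        else:
            present = [str(lvl) for lvl in spec.levels if (groups == str(lvl)).any()]
            res = log_rank(times, d, groups) if len(present) > 1 else None
        for lvl in spec.levels:
            m = groups == str(lvl)
            if not m.any():
                continue
            rate = person_time_rate(times, d, mask=m)
            rows.append(
                {
                    "covariate": spec.name,
                    "level": str(lvl),
                    "failures": rate.failures,
                    "person_time": rate.person_time,
                    "rate_per_1000": rate.rate_per_1000,
                    "ci_low": rate.ci_low,
                    "ci_high": rate.ci_high,
                    "logrank_p": res.p_value if res is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
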