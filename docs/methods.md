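# Methods

## Cause-specific competing-risks AFT models

Death is classified into two mutually exclusive causes (HF-related,
non-HF-related); only the first event is observed, and subjects whose vital
status runs out are right-censored. The package analyses each cause with
its own accelerated-failure-time model in which the competing cause is
recoded as censoring. This cause-specific construction matches the
classical latent-failure-time view: if each cause has an independent latent
time given covariates, the cause-specific censored likelihood

    sum_i [ d_i log f(t_i) + (1 - d_i) log S(t_i) ]

is the correct likelihood for that cause's parameters, which is why
parameter recovery against the synthetic generator (below) is well-posed.
The estimates are cause-specific quantities; they are deliberately not
presented as marginal cumulative-incidence curves (no Aalen–Johansen or
subdistribution-hazard machinery is included).

Three families share the linear predictor `x·β` (leading intercept):
Weibull and log-logistic on the rate scale `λ = exp(x·β)` with shape
`p > 0`, log-normal on the log-time location scale with spread `δ > 0`
(variance of log time). All reporting happens on the time-ratio scale
(`exp(−β_j/p)` or `exp(β_j)`), where TR < 1 uniformly means shorter
survival; the conversion is applied per posterior draw using that draw's
own ancillary value, never by refitting.

Numerical care: log-densities and log-survivals are evaluated in log space
throughout (`logaddexp` for the log-logistic denominator, `log_ndtr` for
the normal tail), so large `λ t^p` degrades to `−inf` rather than
overflowing; a non-finite likelihood contribution raises an error naming
the subject.

## Priors and sampler

Coefficients carry independent Normal(0, v) priors with v = 10,000 by
default — diffuse enough that, at the data sizes used here, the posterior
is likelihood-dominated. The positive ancillary parameter is sampled as
`log p` (or `log δ`) with the same Normal(0, v) prior.

The sampler is an adaptive random-walk Metropolis on θ = (β, log
ancillary): a joint Gaussian proposal whose covariance tracks the running
posterior covariance (Welford accumulation, Cholesky refresh every 200
iterations) and whose global step size follows a Robbins–Monro recursion
toward the 0.234 acceptance target. Both adaptations run during burn-in
only, so the retained segment is a genuine Markov chain. Chains start at
the MLE found by a short Nelder–Mead + BFGS optimization (falling back to
zeros), defaults are 2 chains × 20,000 iterations with 10,000 burn-in, and
every run is reproducible bit-for-bit from one integer seed
(`numpy.random.SeedSequence` substreams per chain). Convergence is
monitored with split-Rhat (each chain halved); values above 1.1 emit a
warning rather than an error. Post-burn-in acceptance rates on the
standard synthetic cohorts sit in [0.15, 0.5].

Point estimates are posterior medians and intervals are equal-tailed
2.5–97.5 percentiles, which accommodates the asymmetry of TR posteriors. A
covariate is called "significant" when its 95% credible interval excludes
TR = 1 — a reporting convention in the spirit of a 0.05 level, not a
frequentist test.

## Model comparison

All three criteria are computed from the pointwise log-likelihood matrix
(draws × subjects):

* **DIC** = D̄ + p_D with p_D = D̄ − D(θ̄); θ̄ is the posterior mean taken
  on the sampling scale (β, log ancillary) and back-transformed, keeping
  p_D invariant to the positivity reparameterization. Negative p_D warns.
* **WAIC** = −2(lppd − p_WAIC), with lppd via log-sum-exp and p_WAIC the
  summed *sample* variance (ddof = 1) of pointwise log-likelihoods.
* **LPML** = Σ log CPO_i with the harmonic-mean CPO estimator, evaluated in
  log space. The harmonic mean needs only the pointwise matrix; its error
  is bounded in the test suite against exact leave-one-out refits on a
  20-subject cohort (agreement within 0.5 on the total).

Families are ranked by DIC alone; WAIC and LPML are reported alongside.
Ties break to the first family in the fixed order (Weibull, log-normal,
log-logistic) and are flagged. On a single simulated cohort the winning
family is a stochastic outcome — with n = 400 and ~50% events the
generating family wins in roughly 9 of 10 replicates, and the test suite
asserts exactly that majority property rather than the winner of one draw.

## Study pipeline

Per cause: family selection → univariable screen → multivariable model →
prior-variance sensitivity. Family selection by default runs once on the
pooled all-cause view (one comparison table for the study); a per-cause
scope is available. The univariable screen fits each covariate alone
(multi-level covariates enter as their whole dummy or trend block) and
keeps covariates with any significant column; the multivariable model
joins the kept covariates. An empty screen result is recorded as a finding
("no covariate passed"), not a failure. The sensitivity stage refits the
multivariable model at each prior variance in {1, 10, 100, 1000, 10000},
reusing the multivariable-stage seed at every level so the
reference-variance column reproduces the main fit exactly, and flags
design columns whose posterior-median TR moves by more than 10% relative
to the reference — a point-estimate criterion; intervals are reported but
do not enter the flag.

All stage seeds are substreams of the study seed keyed by (stage, cause,
item), so each cause's results are identical whether or not the other
cause runs.

A note on verifying shrinkage: tightening the prior must pull posterior
median |β| toward zero, but between v = 10,000 and v = 1,000 the
theoretical attenuation is of order σ²_like · 9·10⁻⁴ — far below any
achievable MCMC resolution for a data-informed coefficient. The test suite
therefore asserts adjacent monotonicity across the grid with a small
Monte-Carlo allowance (0.03 on the |β| median, with 60,000 retained draws
per level) plus a strict overall decrease from v = 10,000 to v = 1.

## Descriptive layer

Person-time is measured in person-months and rates are reported per 1000
person-months — the scale on which a ~435-subject, five-year cohort yields
rates of order 10. Rate intervals are exact Poisson (Garwood,
chi-square-quantile) limits on the count. Kaplan–Meier uses the
product-limit estimator with Greenwood variance; intervals default to the
plain probability scale truncated to [0, 1] (a complementary log-log
option exists). At tied death/censoring times the death takes precedence
(censored subjects stay in the risk set at that instant). The log-rank
test is the standard observed-minus-expected chi-square over pooled event
times, with an ordered-scores 1-df trend variant for ordinal covariates
and for quartile-banded continuous ones. All descriptive quantities are
cause-specific (competing deaths censored), mirroring the modeling layer.

## Synthetic cohort generator

The generator draws covariates from configurable marginals (Bernoulli,
ordinal/categorical with level probabilities, normal), one latent time per
cause from that cause's AFT family at the subject's linear predictor, and
censoring from two streams: an administrative horizon (default 64 months,
an enrolment-window-to-follow-up span) and an optional exponential dropout
stream standing in for subjects whose vital status could not be
ascertained. The observed record is the minimum with the cause of the
minimum as the event. The truth record (per-cause parameters, per-subject
latent times) is carried alongside for recovery tests.

The registry-like preset (`rashf_like`, n = 435) uses marginals from a
published heart-failure cohort table (61.1% male, 88.3% chest pain, 34%
dyspnea, mean age 56.57 with SD 13 chosen to respect an observed 14–95
range, ...), Weibull time structure with shape 1.1 for both causes, true
time ratios at the published multivariable point estimates (e.g. chest
pain 0.41 / 0.38, hyperlipidemia 0.34 / 0.60), dropout hazard
0.004/month, and intercepts −9.776 / −7.707 calibrated once by a
200,000-subject simulation so the expected death fractions sit at 36.8%
(HF) and 22.3% (non-HF); at n = 435 realized fractions vary by a few
points across seeds. The diabetes prevalence was left out of the preset
because its source row is corrupt in the available table text.

What the generator does *not* emulate — and hence what passing tests do
not establish about real registry data: correlation between covariates,
dependence between the two latent cause times, time-varying covariate
effects, informative censoring, measurement error, and missingness (the
loader rejects incomplete rows rather than imputing). Recovery results
certify the estimation machinery under the model's own assumptions, not
the clinical conclusions of any particular cohort.

Other fixtures: `weibull_truth_n800` (three balanced binary covariates,
TRs 0.5/0.7/1.0, shape 1.3), `lognormal_truth_n400` (location ln 35,
spread 0.8), and `tiny_n20` for brute-force oracles.

## Problem sizes and defaults used in validation

The shipped test suite and acceptance script run single-CPU in a few
minutes by choosing moderate problem sizes: study-pipeline fits use 2
chains × 4,000–6,000 iterations (half burn-in), replicate experiments use
10–20 cohorts of n = 400–800 with single chains of 4,000 iterations, and
the sensitivity-monotonicity check trades a small cohort (n = 60) for
long chains. These sizes were chosen as the package's own validation
conditions; production analyses should use the 20,000-iteration default
and inspect split-Rhat and acceptance rates in the fit diagnostics.

## Known limitations

* Random-walk Metropolis mixes slowly for designs with many correlated
  columns; the full registry design (~17 columns) is near the practical
  comfort limit. No HMC/NUTS backend is provided.
* The harmonic-mean CPO estimator is known to have heavy-tailed error for
  influential observations; the exact-LOO bound is verified only at small n.
* DIC on a single realization can prefer a neighbouring family
  (Weibull vs log-logistic) when censoring hides the tail; family
  identification statements are majority-over-replicates statements.
* KM confidence intervals on the plain scale can hit the [0, 1] clamps in
  small strata; the log-log option avoids this at the cost of asymmetry.
* The generator's latent times are independent across causes by
  construction; nothing here identifies or tests dependence between
  competing risks.
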