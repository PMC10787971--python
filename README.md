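# bayesaft

Bayesian accelerated-failure-time (AFT) competing-risks survival analysis
for registry-style cohorts, built around the kind of question a heart-failure
registry poses: *which factors shorten a patient's survival time, separately
for death from heart failure and death from other causes?*

## The model

Each subject contributes a follow-up time `t_i` (months) and an event code
(censored, HF-related death, non-HF-related death). For a chosen cause, the
competing cause is treated as censoring (`d_i = 1` only for that cause's
deaths) and a parametric AFT model is fitted with the censored likelihood

```
L(β | X, t) = ∏_i f(t_i)^{d_i} · S(t_i)^{1 − d_i}
```

Three families are supported, all driven by the linear predictor `x·β`:

| family        | survival function                 | time ratio per unit of x_j |
|---------------|-----------------------------------|----------------------------|
| Weibull       | `S(t) = exp(−λ t^p)`              | `TR_j = exp(−β_j / p)`     |
| log-logistic  | `S(t) = 1 / (1 + λ t^p)`          | `TR_j = exp(−β_j / p)`     |
| log-normal    | `S(t) = 1 − Φ((ln t − μ)/√δ)`     | `TR_j = exp(β_j)`          |

with `λ = exp(x·β)` (Weibull, log-logistic) or `μ = x·β` (log-normal).
A time ratio below 1 means shorter survival. Coefficients and the log of
the positive ancillary parameter carry independent `Normal(0, 10000)`
priors (effectively non-informative); the posterior is sampled by adaptive
random-walk Metropolis, and every covariate is reported as the posterior
median TR with an equal-tailed 95% credible interval, flagged significant
when the interval excludes 1.

On top of the single-model machinery the package provides the full study
pipeline: DIC/WAIC/LPML family comparison, univariable screening followed
by a multivariable model per cause, prior-variance sensitivity analysis
over the grid {1, 10, 100, 1000, 10000} with a 10%-change flag, and a
descriptive layer (person-time rates with exact Poisson intervals,
Kaplan–Meier curves, log-rank tests). A seeded synthetic-cohort generator
with known competing-risks AFT truth makes every stage testable.

## Worked example

Simulate an 800-subject cohort whose HF-cause truth is Weibull with time
ratios 0.5 / 0.7 / 1.0 on three balanced binary covariates, then fit the
cause-specific Bayesian Weibull AFT model:

```python
import bayesaft as ba
from bayesaft import synthetic_data as sd

g = sd.generate(sd.weibull_truth_config(seed=11))
view = ba.cause_specific_view(g.cohort, ba.Cause.HF)

draws = ba.run_mcmc(
    view, "weibull", ba.PriorSpec(10_000),
    ba.MCMCConfig(n_chains=2, n_iter=4000, n_burnin=2000, seed=1),
)
summary = ba.summarize(draws, ba.Cause.HF)
for tr in summary.time_ratios:
    flag = "  *" if tr.significant else ""
    print(f"{tr.name}: TR = {tr.tr:.2f} ({tr.ci_low:.2f}-{tr.ci_high:.2f}){flag}")
```

prints

```
x1: TR = 0.54 (0.47-0.62)  *
x2: TR = 0.77 (0.67-0.88)  *
x3: TR = 1.09 (0.95-1.28)
```

The posterior medians sit near the generating ratios: `x1` halves survival
time (interval well below 1, significant), `x2`'s effect of 0.7 is
recovered, and the null covariate `x3` straddles 1. The same cohort can be
pushed through the whole plan — family selection, screening, multivariable
fit and sensitivity grid — with `ba.run_study(g.cohort, ba.StudyConfig())`.

From the shell, the pipeline is driven by three subcommands:

```
bayesaft simulate  --preset rashf_like --seed 7 --out data/
bayesaft describe  --cohort data/cohort.csv --out desc/
bayesaft run-study --cohort data/cohort.csv --config study.yaml --out report/
```

Every run writes delimited report tables plus a manifest with seeds and
file hashes, so reruns are bit-for-bit reproducible.

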