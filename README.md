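# lognnc — distributional regression for mobile air-quality measurements

Walking campaigns with instrumented backpacks produce dense, spatially
resolved pollutant measurements — and three statistical headaches at once:
the concentrations are strongly right-skewed, consecutive 10-second
readings are correlated in space and time, and filter-based black-carbon
monitors add zero-mean instrument noise large enough to make many readings
**negative** at urban background levels. Dropping those negatives and
fitting a lognormal model — the common practice — biases every covariate
effect toward zero.

`lognnc` implements a Bayesian distributional regression framework for such
data:

* **Lognormal model** for strictly positive concentrations (PM2.5-like):
  `log Y ~ N(mu, sigma^2)` with additive predictors for both the mean

  `mu(x, s, t) = eta_mu(x) + gamma_space(s) + gamma_time(t)`

  and the log standard deviation

  `log sigma(x, s, t) = eta_sigma(x) + gamma_space(s) + gamma_time(t)`,

  where each `eta` combines linear effects, reference-coded categorical
  effects (street class, street configuration, wind direction, weekday,
  season, ...), penalized cubic regression splines (hour of day, traffic
  counts), and zero-mean latent error processes: a first-order Gauss-Markov
  random field over route segments and a Gaussian process with exponential
  correlation `exp(-|dt|/range)` over campaign time.

* **Lognormal-normal convolution (logNNC) model** for noisy equivalent
  black carbon: the observation is `Y~ = Y + eps` with `eps ~ N(0,
  lambda^2)`, so `Y~ ~ logNNC(mu, sigma^2, lambda^2)`. The density has no
  closed form; it is evaluated by mode-centered segmented Gauss-Legendre
  quadrature of the convolution integral. The noise level gets its own
  predictor `log lambda(t) = eta_lambda + gamma_time(t)` (intercept plus a
  temporal latent process — instrument behavior should not depend on
  covariates).

Inference is penalized-likelihood MAP optimization (blockwise Newton
backfitting) followed by blockwise Metropolis-Hastings with
curvature-informed Gaussian proposals; spline and latent-field blocks carry
Gaussian quadratic-penalty priors with inverse-gamma variance
hyperpriors, linear coefficients improper flat priors. Effects are
summarized with 95% credibility intervals (significant = CI excludes zero)
on the log, log2 or percent scale.

The package also ships the matching model-criticism tools (quantile
residuals `r = Phi^-1(F(y|x))`, normal Q-Q summaries, within-round residual
autocorrelation, deconvolved signal/noise density curves), a four-model
comparison harness (Final Model vs constant-sigma, truncated-lognormal and
Gaussian alternatives), and a synthetic campaign generator that emulates a
Leipzig-like layout (2 rounds/day, 2 seasons, traffic counts on the primary
road, noise sd ~ 0.6 ug/m3) and a Rome-like layout (3 rounds/day, ambient
covariate, qualitative traffic) with full ground truth for every record.

## Worked example

```python
import numpy as np
from lognnc import (leipzig_like, make_route, simulate_campaign,
                    leipzig_spec, fit_map, quantile_residuals, residual_acf)

template = leipzig_like(seed=7)            # ~20,000 records, known truth
route = make_route(template)
records, truth = simulate_campaign(template, route)
print(f"n = {len(records)}, negative share = {(records.value < 0).mean():.3f}")

fit = fit_map(records, leipzig_spec(latent=True), "lognnc", route=route)
tab = fit.coef_summary
primary = tab[(tab.param == "mu") & (tab.coef == "strclass[primary]")]
print("mu strclass[primary]:", round(float(primary.estimate.iloc[0]), 3),
      "(truth", round(truth.coefficients["mu"]["strclass[primary]"], 3), ")")
lam = float(np.mean(fit.predict_params()["lam"]))
print("fitted noise sd:", round(lam, 3),
      "(true mean", round(truth.per_record["lam"].mean(), 3), ")")
r = quantile_residuals(fit, records)
print(residual_acf(r, [10.0, 300.0]))
```

Output:

```
n = 20160, negative share = 0.099
mu strclass[primary]: 0.953 (truth 0.952 )
fitted noise sd: 0.695 (true mean 0.684 )
   lag_s       acf  n_pairs
0   10.0  0.017107    20112
1  300.0  0.009239    18720
```

About 10% of the simulated eBC records are negative — pure instrument
noise at low concentrations, which the convolution likelihood uses rather
than discards. The primary-street effect is recovered on the log scale
(0.95 ~ log 2.59, i.e. a ~159% concentration increase over a park), the
fitted noise sd tracks the drifting truth, and the latent fields leave only
modest residual autocorrelation at one sampling step.

The same models run from the shell:

```sh
lognnc simulate --template leipzig_like --seed 7 --out campaign/
lognnc fit campaign/records.csv --variant final --map-only --out fit/
lognnc diagnose campaign/records.csv --variant model2 --map-only --out diag/
lognnc compare campaign/records.csv --variants final,model2 --map-only --out cmp/
```

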