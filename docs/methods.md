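# Methods

## Models

Pollutant concentrations from mobile measurements are modeled
distributionally: every distribution parameter gets its own additive
predictor rather than only the mean.

**Lognormal (error-free pollutants).** `Z = log Y ~ N(mu, sigma^2)` with

```
mu(x, s, t)        = eta_mu(x)     + gamma_mu_space(s)    + gamma_mu_time(t)
log sigma(x, s, t) = eta_sigma(x)  + gamma_sigma_space(s) + gamma_sigma_time(t)
```

**Lognormal-normal convolution (noisy eBC).** Filter-based black-carbon
monitors report differences of consecutive attenuation readings; at 10-s
resolution the result is the true concentration plus approximately
Gaussian, zero-mean instrument noise, so readings can be negative. We model
`Y~ = Y + eps`, `eps ~ N(0, lambda^2)` independent of `Y`, giving

```
Y~ ~ logNNC(mu, sigma^2, lambda^2)
f(y~) = E_Z[ N(y~ - exp(mu + sigma Z); 0, lambda^2) ],  Z ~ N(0,1)
log lambda(t) = eta_lambda + gamma_lambda_time(t)
```

The noise predictor carries no covariates: instrument behavior should not
depend on the street environment, but the noise level does drift slowly as
the internal pump ages, which the temporal latent process absorbs.

Conditional on the latent processes, observations are independent. The
latent processes are zero-mean devices for spatiotemporal correlation, like
random intercepts in mixed models: a first-order intrinsic Gauss-Markov
random field over adjacent route segments (precision = graph Laplacian,
sum-to-zero constrained) and a Gaussian process with exponential
correlation `exp(-|dt|/range)` over absolute campaign time.

## Additive predictors

Terms: intercept, linear effects (wind speed; log ambient concentration for
Rome-style data), reference-coded categorical effects (wind-direction
sector, street class, street configuration, street activity, qualitative
traffic, weekday, season), penalized cubic regression splines (hour of day;
traffic counts), and the latent fields. No interactions. Links: identity
for `mu`, log for `sigma` and `lambda`.

Splines are cubic B-splines with knots at empirical quantiles (default 8
knots -> 10 basis functions) and an exactly integrated squared-second-
derivative penalty (two-point Gauss-Legendre per knot interval is exact for
the piecewise-quadratic product of second derivatives). Each spline is
reparameterized into the orthonormal null space of its sum-to-zero
constraint over the training observations, keeping the intercept
identifiable while leaving linear functions unpenalized. The hour-of-day
spline is non-cyclic: the emulated measurement windows never wrap midnight.
The traffic-count spline is constrained to zero mean over primary-road
observations and is identically zero elsewhere, so street-class effects
retain their interpretation.

Wind direction uses 8 sectors (N through NW); reference levels are
park/pedestrian street class, open configuration, weekend, summer, and the
most frequent wind sector, so categorical effects read as contrasts against
the least-trafficked baseline.

## Latent-field parameterizations

*Spatial.* Segment indicators times an orthonormal basis of the null space
of the constraints; penalty = transformed Laplacian (full rank after
constraints). Besides the sum-to-zero constraint, the field is constrained
orthogonal to the segment-level street attributes (restricted spatial
regression). Streets of one class are contiguous along a walking route, so
an unconstrained intrinsic field could absorb street-class contrasts nearly
free of penalty; restricting it makes the fixed effects well-defined
estimands. The synthetic generator draws its spatial truth in the same
restricted space for the same reason.

*Temporal.* Knot-based predictive process: coefficients are field values at
knot times (quantiles of observed times, default 50), design row
`r(t,u) R_uu^{-1}`, penalty `R_uu^{-1}`. The exponential kernel decays
linearly at short lags, so the low-rank variance deficit is roughly (knot
gap)/(2 range); resolving a 5-10-minute-range process across a multi-day
campaign with 50 knots is intentionally coarse smoothing, and analyses
targeting the serial structure itself should raise `n_knots` (the
decorrelation analysis uses 150). The default range is 600 s; a profiling
helper over {30 s, 2 min, 10 min, 1 h} exists, but the default fits use the
declared range — profiling at every fit was not worth its cost at these
problem sizes.

Each field has its own variance hyperparameter with an
inverse-gamma(0.001, 0.001) prior; fields for `mu`, `sigma` and `lambda`
share nothing.

## Likelihood evaluation

The convolution integral is evaluated per observation by segmented
Gauss-Legendre quadrature in the latent standard-normal variable `z`: a
Newton-refined mode search (guarded by a coarse scan plus the
signal-matching point `(log y - mu)/sigma`) locates the integrand's peak
and curvature scale `s`; the window `mode +- 7 min(s,1)` gets a
Gauss-Legendre rule with twice the requested node budget (default budget
64, i.e. 128 nodes) and two outer segments covering the remaining prior
mass get 24 nodes each. A rescaled Gauss-Hermite rule was tried first and
fails here: the integrand pairs a sharp kernel mode with a prior-scale
tail ("shelf"), defeating adaptive GH's Gaussian-shape assumption, while
segmented GL is shape-agnostic. Terms are combined by log-sum-exp;
`exp(mu + sigma z)` is clamped at `exp(60)`. Worst-case relative error
against adaptive quadrature over the test lattice (mu in {-1,0,1}, sigma in
{0.2,0.8,1.5}, lambda in {0.3,0.6,1.2}, y in {-1,0,0.5,2,10}) is ~4e-9 at
the default budget; the fitting path uses a 24-node budget (worst ~3e-5).
Below `lambda = 1e-8` the pure lognormal branch is used.

The CDF uses a fixed composite-Simpson grid in `z` (step 0.02 over
[-9, 9]): a fixed positive-weight grid makes `F` exactly non-decreasing in
`y`, which quantile residuals rely on.

Score and curvature with respect to the three predictors are differentiated
through the fixed quadrature (posterior node weights `p_k`), giving exact
gradients of the approximated likelihood and the IWLS working weights
(clamped positive where the observed information is locally negative). A
numba-compiled fused loop reproduces the reference numpy implementation to
~1e-13 and is used automatically for fitting; a unit test pins the
equivalence.

## Fitting

**MAP.** Cyclic blockwise Newton with step halving on the penalized
log-likelihood; blocks are the parametric coefficients per parameter, each
spline, and each latent field. Variance hyperparameters update by an
EM-type step, `tau^2 = (2b + beta'K beta + tr(K H^{-1})) / (rank + 2a +
2)`: the trace term (posterior covariance of the block) prevents the
well-known collapse of the joint (beta, tau^2) mode at zero, which a pure
conditional-mode update exhibits and which silently zeroes latent fields.
Initialization: `mu`/`sigma` intercepts from moments of log positive
values; `lambda` from the root mean square of the negative observations.
Non-convergence after the cycle budget is flagged on the result, not
raised.

**MCMC.** Blockwise random-walk Metropolis-Hastings started at the MAP.
Proposal covariance per block = inverse of the block-conditional curvature
(X'WX + K/tau^2), scaled by 2.38/sqrt(dim); curvature and scalar scale
adapt every 100 iterations during burn-in only (targeting ~25% acceptance),
so detailed balance holds for retained draws. Variance hyperparameters are
Gibbs-updated from their conjugate inverse-gamma conditionals. Defaults:
3000 iterations, 1000 burn-in, thinning 2; the replicate studies below use
shorter chains (1200/400/2), which empirically suffice for 95%-interval
calibration at those problem sizes. Acceptance rates outside (5%, 95%) are
reported as warnings on the result. Effects are declared significant when
the 95% interval excludes zero; the percent scale reports
`100 (exp(beta) - 1)`.

## Diagnostics

Quantile residuals `r = Phi^-1(F(y|x))` are computed at posterior-mean
(or MAP) parameters — one Q-Q curve per model; `F` in {0,1} (negatives
under a truncated lognormal fit would give `r = -inf`) is clipped to +-8
and excluded from the finite mask. Autocorrelation is computed within
rounds only, since cross-round pairs mix day effects into the serial
structure. The deconvolution view aggregates per-record lognormal signal
densities, `N(0, lambda^2)` noise densities and their convolution over a
record subset, with bands from posterior draws. The variance-explained
share `s^2/(s^2 + lambda^2)` quantifies the ceiling any concentration
model faces under instrument noise: for true concentrations 0.44 and 1.25
ug/m3 and noise sd 0.6 the ceiling is ~48%.

## Model-comparison harness

Final Model = logNNC with modeled `sigma`. Model 1 = logNNC with
intercept-only `sigma`. Model 2 = lognormal after dropping `y <= 0` (zeros
are excluded because the lognormal density is undefined there). Model 3 =
Gaussian on the original scale; its coefficients are flagged as not
quantitatively comparable. The attenuation experiment simulates a
low-concentration regime (park median ~0.44 ug/m3, noise sd 0.6, n ~ 4000,
effects on wind speed, street class and season only) and reports bias and
shrinkage per effect for Model 2 vs the Final Model, using MAP point
estimates — the compared quantities need no posterior draws.

## Synthetic campaigns

The generator is the package's study-condition definition, not a test
fixture. Leipzig-like: 60 path segments with street class, configuration
(and counts on the primary block) in contiguous blocks; 2 rounds/day in
5:00-11:00 and 14:00-17:30 windows; 24 days, half winter; 10-s records
(~20,160 per campaign); additive noise sd 0.6 ug/m3 with a slow log-scale
random walk across rounds (sd 0.05) emulating pump aging. Rome-like: 3
rounds/day (8:00-10:30, 13:30-15:30, 18:00-20:00), ambient-concentration
covariate with AR(1) round dynamics, 4-level qualitative traffic, street
activities. Default effect sizes convert reported percentage changes via
`log(1 + pct/100)`: +159%/+114% primary street, +160% winter, +88% weekday
(Rome-like), +55%/+20% street canyon; wind-speed slope -0.05 per m/s;
positive `sigma` effect (+0.25) on primary streets. Wind speed is
gamma-distributed per round, direction an 8-sector categorical, traffic
counts follow a smooth two-peak diurnal curve; covariates are drawn
independently, which real campaigns (wind-season dependence, for one) are
not. The smooth hour and traffic truths are centered exactly as the fitted
splines are, so fixed effects remain comparable estimands. A 1-s-to-10-s
median aggregator (windows with fewer than 6 valid points dropped) mirrors
the instrument pre-processing for users with raw data.

What passing tests show — and don't. Recovery and coverage results
demonstrate internal consistency: data generated by the stated mechanism
are recovered by the matching model. They do not validate the lognormal
assumption, Gaussian noise, or covariate independence on real instruments;
the residual diagnostics exist precisely because real data will deviate
(real eBC noise, for instance, is somewhat heavier-tailed than Gaussian).

## Problem sizes and numerical choices

Replicate studies run at reduced sizes chosen once: interval coverage uses
20 campaigns of 16 rounds x 120 records (wind-direction truth zeroed — an
8-level nuisance factor at n ~ 1900 adds nothing to a calibration check)
with 1200-iteration chains; residual calibration uses 20 intercept-only
fits at n = 2000; the attenuation comparison 11 runs at n ~ 4200; the
decorrelation check one campaign of n ~ 5000 with a 150-knot temporal
field. The full-size recovery fit (n ~ 20,160, all terms and latent
fields) uses MAP estimates. Degenerate inputs: single-level categorical
terms produce zero columns with a warning; disconnected route graphs raise
with the component list; unknown categorical levels or segment ids at
prediction time raise naming the offender; `burn_in >= n_iter` raises.
Ties in spline knots from low-cardinality covariates collapse to unique
knots and raise if fewer than four remain.

## Known limitations

Blockwise proposals mix slowly when `mu`, `sigma` and `lambda` are jointly
weakly identified (near-zero concentrations under heavy noise); the
reported intervals are calibrated at the tested sizes but conservative
chain lengths are advisable for final analyses. Interval coverage inherits
the conditional-independence assumption: with unmodeled fine-grained
correlation, intervals come out slightly narrow (the latent processes
decorrelate widely, not entirely). The predictive-process temporal field
underestimates short-lag variance between knots. No skew or heavy-tailed
noise distributions; no automated variable selection; no 2-D off-route
kriging; no GPS/geographic processing.
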