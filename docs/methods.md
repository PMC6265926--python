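# Methods

## Model and priors

The outcome is Bernoulli with a logit link; the linear predictor is the sum
of an intercept, treatment-coded categorical fixed effects, RW2-smoothed
functions of continuous covariates, and an ICAR district field.

**Fixed effects.** Diffuse priors are implemented as proper N(0, 10⁶)
Gaussians per coefficient. At survey scales (thousands of records, |β| of
order 1) the prior contributes at most 10⁻⁶ to any precision entry and is
indistinguishable from a flat prior; it exists so the joint update is a
proper Gaussian.

**RW2 smooths.** Each continuous covariate is mapped onto a grid: the
sorted distinct values when there are at most `max_grid` of them, otherwise
`max_grid` equal-width bin midpoints. Both age covariates are recorded in
whole years, so the grid is (nearly) equally spaced and the penalty is the
classical second-difference form `K = D₂'D₂` (rank m−2, null space =
constant and linear vectors). Grid spacing is treated as equal even for bin
midpoints. Age at first cohabitation is generated within [10, 49]; values
above the eligible-age ceiling would create isolated grid tails.

**Spatial field.** `Q = diag(n_j) − A` from the symmetric neighbour lists.
Disconnected maps are accepted for fitting: the rank of `Q` is D minus the
number of components and each component carries its own sum-to-zero
constraint.

**Hyperpriors.** Every precision (per smooth, spatial, optional iid
district effect) gets Gamma(shape 1, rate 0.0005) — the conventional weakly
informative default of structured-additive-regression software; both
parameters are configurable. The conjugate update uses the *rank* of the
penalty (m−2 for RW2, D−c for ICAR) as its degrees of freedom.

## Sampling

Pólya-Gamma augmentation: `ω_i ~ PG(1, η_i)` renders the likelihood
Gaussian in the coefficients. Each Gibbs iteration draws (a) all `ω_i` with
an exact Devroye-type alternating-series rejection sampler (JIT-compiled;
the closed-form mean `tanh(z/2)/(2z)` is the test oracle), (b) the complete
coefficient vector jointly from `N(P⁻¹ Z'(y−½), P⁻¹)` with
`P = Z'ΩZ + blockdiag(priors)` via one dense Cholesky factorisation — the
stacked dimension is ~30–140 for all supported configurations, so a joint
draw is cheaper and mixes better than blockwise updates — and (c) each
precision from its Gamma full conditional.

**Identifiability.** The constant direction of each smooth/spatial block is
likelihood-flat against the intercept *and against the other blocks'
constants*. Two measures handle this: each block mean gets a proper N(0, 1)
prior (a soft sum-to-zero constraint that keeps the joint precision
positive definite), and after every joint draw the block mean is subtracted
and added to the intercept — an exact reparametrisation that leaves the
linear predictor unchanged, keeps the intercept interpretable, and makes
every retained draw sum to zero to machine precision. For a disconnected
map only the global mean can be moved into the intercept exactly; the
per-component recentring is applied when draws are stored.

**Defaults.** 12,000 iterations, 2,000 burn-in, thinning 5; the seed must
be given explicitly. Per-record PG draws are seeded per iteration from the
fit-level generator, so runs are bit-reproducible.

**Degenerate inputs.** Non-finite states abort with the iteration index; a
spatial model without a graph, districts absent from the graph, unseen
factor levels at prediction time, and constant smooth covariates are all
rejected with named errors.

## DIC

`D̄` is the mean of per-draw Bernoulli deviances (computed from η via
log-sum-exp, so boundary probabilities cannot overflow); the plug-in uses
the posterior mean of the *linear predictor* — η is linear in all
coefficients, so this equals plugging in the posterior means of β, the
smooth grids and the spatial field, the standard canonical-parameter
plug-in. `DIC = D̄ + p_D` holds exactly by construction. A batch-means
Monte-Carlo standard error of `D̄` is provided to scale comparisons.
Published DIC tables in this literature do not always satisfy the identity
between their printed `D̄`, `p_D` and DIC columns; this implementation
keeps the identity exact and reports all three.

## Synthetic-data generator

The generator emulates a DHS-style extract: 6,847 women, 30 districts on a
5×6 rook lattice (a stand-in with the same region count as Rwanda's
district map, avoiding shapefile shipping), 492 clusters nested uniformly
within districts, twelve categorical covariates with marginals taken from
the published descriptive table (the living-children marginals are
internally inconsistent in the source and are renormalised to
0.05/0.18/0.20/0.20/0.37), integer ages from clipped normals (current age
mean 32.8, sd 8, range 16–49; cohabitation age mean 21, sd 4, floor 10,
capped at current age). Default truth effects are the published posterior
log odds ratios; default smooth truths are a monotone decline in current
age and an inverted-U of cohabitation age peaking at 25; the district field
is one ICAR draw (spectral construction on the sum-to-zero eigenspace,
precision τ=4, field sd ≈ 0.27). Users split into modern/traditional
methods at the published 3208:402 ratio.

Because effects are reference-coded their marginal expectation is nonzero,
so the default intercept is calibrated by a fixed-seed Monte-Carlo
bisection to make the *mean success probability* equal the target
prevalence 0.53 (matching the mean log odds instead would overshoot: the
strongly negative no-children effect skews η left).

What the generator does **not** emulate: survey sampling weights and
design-based selection, item nonresponse, cluster-level random effects (an
iid cluster effect is available but off by default, as the fitted models
contain none), real district adjacency, or covariate dependence beyond the
cohabitation-age/current-age ordering. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness to the design features of real survey data.

## Validation studies (desk scale)

Sizes were chosen once to keep the full validation under a few minutes on
one CPU:

* **Quadrature oracle** — intercept-only fit on 35/100 successes, 6,000
  iterations, against a 14,001-point grid posterior; agreement within 0.02
  (typical error ≈ 0.003). A 2-D variant (intercept + one dummy) is tested
  against dense 2-D quadrature.
* **Parameter recovery** — 20 replicates, n = 3,000, model 4 truth with a
  reduced covariate trio (education 4 levels, working, radio; effects
  0.20–0.60), chains 1,500/500/thin 2. Per-coefficient 95% CrI coverage
  must reach 17/20; the acceptance script reports the pooled coverage rate
  over all coefficients and replicates.
* **Smooth/spatial recovery** — one n = 10,000 survey; the current-age
  smooth must correlate ≥ 0.9 with truth over the grid (measured ≈ 0.996).
  The cohabitation smooth is additionally checked with a record-count-
  weighted correlation (measured ≈ 0.94): its grid tail beyond ~35 years
  carries only a handful of records, where the RW2 extrapolates linearly
  and an unweighted correlation mostly measures prior behaviour. District-
  field correlation must reach ≥ 0.7 (measured ≈ 0.9).
* **DIC ranking** — 10 replicate n = 2,000 surveys with clearly nonlinear
  smooth truths (tanh decline, strong inverted-U) plus a τ=2 spatial field;
  model 4 must rank first in ≥ 8/10 (measured 9–10/10). The identity
  `DIC = D̄ + p_D` is asserted exactly on every fit.
* **Screening calibration** — 2,000 null simulations (n = 900, three-level
  covariate independent of outcome); the 5% chi-square screen's rejection
  rate must lie in 0.05 ± 0.01.

## Design choices and limitations

* Estimation is exact MCMC rather than a Laplace-type approximation: the
  analysis contribution is the model, and MCMC permits oracle validation
  (quadrature, closed-form PG moments) at desk scale.
* Pearson chi-square without Yates correction (multi-level tables; the
  correction is switchable). Percentages round half-up to one decimal, the
  print convention of survey reports. Zero-margin levels are dropped from
  tests with a warning rather than erroring.
* Credible intervals for odds ratios are equal-tailed coefficient
  quantiles exponentiated; by monotonicity this equals the equal-tailed
  interval of the OR draws.
* The chi-square screen is a descriptive gate, not variable selection
  inside the fitter; the model's covariate set is always explicit
  configuration.
* Smooths are univariate only (no tensor products or varying
  coefficients); no survey-weighted likelihood; no BYM convolution beyond
  the optional iid district toggle; no WAIC/LOO.
* Map rendering consumes GeoJSON polygons directly (or draws a heat-grid
  for lattice maps); it never derives adjacency from geometry unless the
  polygon-touching builder is explicitly requested — neighbour lists are
  the source of truth.
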