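# Methods

## The models

All data follow a two-level count design: individuals *i* nested in
populations *j*, a continuous covariate *x_i* ("body size"), counts
*C_ij* ~ Poisson(μ_ij) with log link. The fitted models are

* **naive**: log μ_ij = β₀ + β₁ x_i + u_j, u_j ~ N(0, σ_α²);
* **OLRE**: log μ_ij = β₀ + β₁ x_i + u_j + e_i, e_i ~ N(0, σ_ε²),

where the observation-level random effect *e_i* has one level per row and
absorbs extra-Poisson variation (the Poisson-lognormal model).

## Simulated overdispersion mechanisms

The three generators share the hierarchical skeleton
α_j ~ N(μ_α, σ_α), η_ij = α_j + β x_i, with defaults μ_α = −0.5,
σ_α = 0.5, β = 0.1, 10 populations × 50 individuals and
x ~ N(30, 4) redrawn for every replicate. These defaults put the mean
count near exp(2.5) ≈ 12 and make the fixed-effect variance
(β² · var(x) ≈ 0.16) comparable to the population variance (0.25), so both
bias and r² effects are visible at desk scale. Each mechanism has one
dial:

* **noise** — σ_ε, the SD of lognormal observation noise added to η
  (grid 0.1 … 1.0 in steps of 0.1, i.e. noise:signal SD ratios of 0.2–2);
* **zip** — π, the probability that an observation is replaced by a
  structural zero, applied as an independent Bernoulli mask after Poisson
  sampling (grid 0 … 0.5 in steps of 0.05; π = 0 is the control);
* **negbin** — k, the gamma shape in a gamma-Poisson mixture
  (rate ~ Gamma(shape = k, mean = μ)), giving var = μ + μ²/k
  (grid 5, 4.47, …, 0.77, 0.25).

The generators record the realized latent draws (α_j, ε_i, the
zero-inflation mask), so tests can reconstruct the exact Poisson means.
What the generators deliberately do **not** emulate: covariate-dependent
zero-inflation, random slopes, measurement error in *x*, temporal or
spatial autocorrelation. Passing tests therefore demonstrate behaviour
under clean, exchangeable overdispersion, not under every failure mode of
field data.

## Fitting: Laplace approximation with structured PIRLS

`fit_poisson_glmm` maximizes the Laplace-approximate marginal likelihood.
Two stages:

1. the random-effect SDs are optimized on the log scale with the fixed
   effects profiled inside penalized IRLS (fast, lands near the optimum);
2. fixed effects and log-SDs are then optimized jointly by Nelder–Mead,
   with only the random-effect modes profiled. Stage 2 matters for the
   OLRE model: the Laplace log-determinant carries one curvature term per
   observation and noticeably shifts the intercept if ignored.

The inner solve is exact and O(n) per iteration: eliminating the diagonal
OLRE block rescales the working weights to w/(1 + w σ_ε²); because
populations partition the observations, the population block is diagonal
after that elimination, leaving a 2×2 solve for the fixed effects. The
log-determinant needed by the Laplace objective factors the same way
(Σ log(1 + μ σ_ε²) + Σ_j log(1 + σ_α² Σ_{i∈j} w̃_i)).

Numerical choices: linear predictors are clipped at ±30; SDs are bounded
in [10⁻⁶, 10] on the SD scale and estimates below 10⁻⁴ are reported as 0
(boundary); PIRLS uses step-halving on the penalized deviance with
relative tolerance 10⁻¹⁰; the outer Nelder–Mead runs at
fatol 10⁻⁸ with up to 3 jittered restarts on failure. Starting values:
fixed effects from a Poisson GLM ignoring random terms, SDs at 0.3.
Wald SEs for the fixed effects are the inverse of the 2×2 profiled
information at the optimum with variance parameters held fixed — the same
convention as lme4's `vcov`, against which the fitter is cross-checked in
the test suite (estimates to ~10⁻³, log-likelihood to ~10⁻²).

Convergence failures are returned (flagged, not raised) so unattended
grid sweeps continue; summaries exclude non-converged replicates and
report their count.

## Reference fitters (ZIP and NB mixed models)

`fit_zip_mixed` and `fit_nb_mixed` maximize the exact marginal likelihood,
integrating the population intercept by adaptive Gauss–Hermite quadrature:
per population the integrand is re-centred at its conditional mode (damped
Newton with numerical derivatives) and re-scaled by the local curvature
before applying the Hermite rule. 15 nodes are the default; estimates move
by < 10⁻³ when increased to 25. The ZIP density uses the standard
normalized form — P(0) = π + (1−π)e^{−μ}, P(y>0) = (1−π)·Poisson(y; μ) —
and π is a single constant on the logit scale, matching the generator. In
the NB fitter k is estimated on the log scale; when the likelihood at the
Poisson limit is within 1 log-unit of the optimum, k is unidentified
upward and the fit is reported at the 10⁶ cap with a boundary flag.
Wald SEs come from a central-difference Hessian, delta-transformed to the
π and k scales. Both fitters reproduce glmmTMB estimates to ~10⁻⁴ on
simulated datasets.

## Dispersion diagnostics

The point statistic is Σr²/df with conditional Pearson residuals
r_i = (y_i − μ̂_i)/√μ̂_i (μ̂ includes all conditional modes). Residual df
default to n − p − (one per random *term*); the convention charging one df
per random-effect *level* is exposed as `df_mode="levels"` because the df
denominator for GLMMs is genuinely ambiguous. The chi-square p-value is
the upper tail of χ²(df) at Σr².

The parametric bootstrap sidesteps the df question: each replicate redraws
every random effect from its estimated distribution, simulates Poisson
counts, refits the same specification (warm-started from the original
estimates — a speed choice that does not change the estimand), and the
dispersion parameter is original SS / bootstrap SS, summarized by its mean
and a 2.5/97.5 percentile interval. More than 20% failed refits aborts
the procedure.

## Variance components and r²

For a Poisson log-link GLMM the latent-scale decomposition is
σ²_fixed = var(β̂₁ x) (sample variance, ddof 1), σ²_random = σ̂_α² (+ σ̂_ε²
when an OLRE is present — classifying the OLRE as random-effect variance
is what makes the OLRE conditional r² balloon toward 0.9 while marginal r²
collapses), and σ²_residual = ln(1 + 1/λ̄), the lognormal
distribution-specific variance. λ̄ is the model-implied mean count
exp(β̂₀ + β̂₁ x̄ + σ²_random/2); the half-variance term is the lognormal
mean correction and can be disabled
(`half_variance_correction=False`) — with counts near 12 the correction
changes σ²_residual only in the third decimal, so both conventions
reproduce the naive marginal r² ≈ 0.35. Marginal r² is σ²_fixed over the
total; conditional r² adds σ²_random to the numerator.

## Orchestration and reproducibility

`run_scenario` simulates and double-fits each replicate; summaries are
replicate means with 95% percentile-bootstrap CIs (1000 resamples).
Replicate *r* of scenario *s* always draws from
`SeedSequence(master_seed, spawn_key=(s, r))`, so results are bit-identical
across runs and independent of execution order; a grid offset lets several
grids share one master seed without stream collisions.

Problem sizes: the package's study configuration is 100 replicates per
scenario (the ten-point noise grid plus single scenarios complete in a few
minutes on one CPU); the test suite exercises a reduced 20-replicate
three-grid sweep as its continuous-integration configuration.

## Known limitations

* The OLRE model's intercept is reported on the latent scale; under heavy
  zero-inflation it is biased (that bias is the phenomenon under study,
  not a fitter defect — the ZIP mixed model recovers the truth).
* Wald SEs condition on the variance parameters; no profile or bootstrap
  CIs for σ_α, σ_ε are provided.
* Only one covariate, random intercepts and the log link are supported —
  the model class of the study design, not a general GLMM engine.
* The single-fit ZIP slope SE varies roughly ±25% across data
  realizations; comparisons of single fits to any fixed reference value
  inherit that realization noise.
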