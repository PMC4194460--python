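# olre-lab

A simulation laboratory for studying — and diagnosing — **overdispersion in
Poisson mixed models of count data**, built around observation-level random
effects (OLRE).

Ecologists and evolutionary biologists routinely model counts (parasite
loads, offspring numbers, behavioural frequencies) with Poisson GLMMs.
Real counts are usually overdispersed: their variance exceeds the Poisson
mean–variance equality, because of unmodelled noise, aggregation, or an
excess of zeroes. A popular remedy is an OLRE — a normal random intercept
with one level per observation, turning the Poisson model into a
Poisson-lognormal model. This package provides everything needed to study
when that remedy works, on data whose truth is known:

* **`synthcounts`** — generators for three overdispersion mechanisms on a
  common hierarchical design (10 populations × 50 individuals, body-size
  covariate *x* ~ N(30, 4), log-scale intercepts α_j ~ N(−0.5, 0.5),
  slope β = 0.1):
  * *extra-Poisson noise*: μ_ij = exp(α_j + βx_i + ε_i), ε_i ~ N(0, σ_ε);
  * *zero-inflation*: Poisson counts independently zeroed with probability π;
  * *negative binomial aggregation*: gamma-Poisson mixing with
    var = μ + μ²/k.
* **`pglmm`** — a Laplace-approximation maximum-likelihood fitter for
  `count ~ bodysize + (1|population)` ("naive") and
  `count ~ bodysize + (1|population) + (1|obs)` ("OLRE") Poisson models,
  with lme4-style Wald standard errors. The penalized IRLS inner loop
  exploits the disjoint population/OLRE block structure, so each fit is
  O(n) per iteration and a full 100-replicate scenario takes seconds.
* **`altmodels`** — zero-inflated-Poisson and negative-binomial mixed
  models fitted by exact marginal ML with adaptive Gauss–Hermite
  quadrature, used to verify parameter recovery when the model matches the
  generator.
* **`dispersion`** — the Pearson dispersion statistic
  (Σr²/df, chi-square test) and a parametric-bootstrap dispersion parameter
  with 95% CI that avoids the residual-degrees-of-freedom ambiguity.
* **`varexpl`** — Nakagawa–Schielzeth marginal and conditional r² for the
  Poisson log link: r²_m = σ²_f/(σ²_f+σ²_r+σ²_d) and
  r²_c = (σ²_f+σ²_r)/(σ²_f+σ²_r+σ²_d), with the distribution-specific
  variance σ²_d = ln(1 + 1/λ̄).
* **`study`** — orchestration of full scenario grids × replicates × both
  model forms, with bootstrap confidence intervals, SE-ratio tables and
  CSV export, plus the `olre-lab` command-line interface.

## Worked example

```python
from olre_lab import (SimScenario, simulate, replicate_rng, fit_poisson_glmm,
                      dispersion_bootstrap, variance_components, r_squared)

scenario = SimScenario(process="noise", grid_value=0.5)   # sigma_eps = 0.5
data = simulate(scenario, replicate_rng(42))

naive = fit_poisson_glmm(data, include_olre=False)
olre = fit_poisson_glmm(data, include_olre=True)
print(f"naive slope {naive.slope_hat:.4f} (SE {naive.slope_se:.4f})")
print(f"OLRE  slope {olre.slope_hat:.4f} (SE {olre.slope_se:.4f}), "
      f"sigma_eps {olre.sigma_eps_hat:.3f}")

disp = dispersion_bootstrap(naive, data, n_boot=100, rng=replicate_rng(43))
print(f"bootstrap dispersion {disp.boot_mean:.2f} "
      f"[{disp.boot_ci_low:.2f}, {disp.boot_ci_high:.2f}]")

for name, fit in (("naive", naive), ("OLRE", olre)):
    r2 = r_squared(variance_components(fit, data))
    print(f"{name}: marginal r2 {r2.marginal:.3f}, conditional r2 {r2.conditional:.3f}")
```

prints

```
naive slope 0.0958 (SE 0.0030)
OLRE  slope 0.0962 (SE 0.0062), sigma_eps 0.470
bootstrap dispersion 4.51 [3.96, 5.11]
naive: marginal r2 0.406, conditional r2 0.808
OLRE: marginal r2 0.263, conditional r2 0.876
```

The naive model's slope SE is half the OLRE model's — ignoring
overdispersion overstates precision — and the bootstrap dispersion of ~4.5
flags the misfit. The OLRE model absorbs the extra variation
(σ̂_ε ≈ 0.47, true 0.5); note how the naive model's marginal r² (0.41) is
inflated relative to the OLRE model's (0.26), while the OLRE conditional r²
(0.88) is dominated by the nuisance OLRE variance and should not be
reported as predictive power.

The same operations are available from the shell:

```bash
olre-lab simulate --process noise --value 0.5 --seed 42 --out counts.csv
olre-lab fit counts.csv --formula 'count ~ bodysize + (1|population) + (1|obs)'
olre-lab diagnose counts.csv --boot 100
olre-lab study --process zip --reps 100 --seed 1 --out study_out/
```

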