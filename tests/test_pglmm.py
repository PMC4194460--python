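"""Fitter tests: quadrature oracle, degenerate cases, recovery, invariances."""

import shutil
import subprocess

import numpy as np
import pytest
from scipy import integrate, optimize, stats
from scipy.special import gammaln

from olre_lab import (
    CountDataset,
    PoissonGLMMFit,
    SimScenario,
    fit_poisson_glmm,
    pearson_residuals,
    replicate_rng,
    simulate,
    simulate_from_fit,
    write_dataset,
)
from olre_lab.pglmm import parse_formula


def quad_loglik_naive(data, beta0, beta1, sigma_alpha):
    """Independent oracle: exact one-factor Poisson GLMM marginal loglik by
    numerical integration (scipy.integrate.quad per population)."""
    total = 0.0
    for j in range(data.n_pop):
        sel = data.population == j
        y, x = data.counts[sel], data.covariate[sel]

        def integrand(u):
            eta = beta0 + beta1 * x + u
            ll = np.sum(y * eta - np.exp(eta) - gammaln(y + 1.0))
            return np.exp(ll) * stats.norm.pdf(u, 0, sigma_alpha)

        val, _ = integrate.quad(integrand, -8 * sigma_alpha, 8 * sigma_alpha, limit=200)
        total += np.log(val)
    return total


class TestLaplaceVsQuadratureOracle:
    def test_loglik_agreement_at_estimates(self, small_poisson_data):
        fit = fit_poisson_glmm(small_poisson_data, include_olre=False)
        exact = quad_loglik_naive(small_poisson_data, fit.intercept_hat,
                                  fit.slope_hat, max(fit.sigma_alpha_hat, 1e-4))
        assert abs(fit.loglik_laplace - exact) < 0.1

    def test_estimates_agree_with_quadrature_mle(self, small_poisson_data):
        fit = fit_poisson_glmm(small_poisson_data, include_olre=False)

        def negll(p):
            return -quad_loglik_naive(small_poisson_data, p[0], p[1], np.exp(p[2]))

        res = optimize.minimize(
            negll,
            np.array([fit.intercept_hat, fit.slope_hat, np.log(max(fit.sigma_alpha_hat, 0.05))]),
            method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-9})
        assert abs(fit.intercept_hat - res.x[0]) < 1e-2
        assert abs(fit.slope_hat - res.x[1]) < 1e-2
        assert abs(fit.sigma_alpha_hat - np.exp(res.x[2])) < 1e-2


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
def test_matches_lme4_glmer(tmp_path, noise_data_mid, noise_fits_mid):
    """Independent cross-check against glmer (Laplace) on one dataset."""
    csv = tmp_path / "dat.csv"
    write_dataset(noise_data_mid, csv)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$population <- factor(d$population); d$obs <- factor(seq_len(nrow(d)))
        m0 <- glmer(count ~ bodysize + (1|population), data=d, family=poisson)
        m1 <- glmer(count ~ bodysize + (1|population) + (1|obs), data=d, family=poisson)
        for (m in list(m0, m1))
          cat(fixef(m), sqrt(diag(vcov(m))),
              unlist(lapply(VarCorr(m), function(v) attr(v, "stddev"))), logLik(m), "\\n")
        """
    )
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    lines = [ln.split() for ln in out.stdout.strip().splitlines()]
    naive, olre = noise_fits_mid
    r_naive = [float(v) for v in lines[0]]
    assert abs(naive.intercept_hat - r_naive[0]) < 5e-3
    assert abs(naive.slope_hat - r_naive[1]) < 5e-4
    assert abs(naive.intercept_se - r_naive[2]) / r_naive[2] < 0.02
    assert abs(naive.slope_se - r_naive[3]) / r_naive[3] < 0.02
    assert abs(naive.sigma_alpha_hat - r_naive[4]) < 5e-3
    assert abs(naive.loglik_laplace - r_naive[5]) < 0.05
    r_olre = [float(v) for v in lines[1]]
    assert abs(olre.intercept_hat - r_olre[0]) < 1e-2
    assert abs(olre.slope_hat - r_olre[1]) < 1e-3
    assert abs(olre.intercept_se - r_olre[2]) / r_olre[2] < 0.02
    assert abs(olre.slope_se - r_olre[3]) / r_olre[3] < 0.02
    # glmer lists (obs, population) stddevs alphabetically: obs first
    assert abs(olre.sigma_eps_hat - r_olre[4]) < 1e-2
    assert abs(olre.sigma_alpha_hat - r_olre[5]) < 1e-2
    assert abs(olre.loglik_laplace - r_olre[6]) < 0.1


class TestDegenerateFits:
    def test_single_population_constant_counts(self):
        m = 4
        data = CountDataset(counts=np.full(30, m), covariate=np.full(30, 2.0),
                            population=np.zeros(30, dtype=int))
        fit = fit_poisson_glmm(data, include_olre=False)
        assert fit.sigma_alpha_hat == 0.0
        assert abs(fit.intercept_hat + fit.slope_hat * 2.0 - np.log(m)) < 1e-3

    def test_non_integer_counts_rejected(self):
        data = CountDataset(counts=np.array([1, 2, 3, 4]), covariate=np.zeros(4),
                            population=np.array([0, 0, 1, 1]))
        data.counts = data.counts.astype(float) + 0.5
        with pytest.raises(ValueError):
            fit_poisson_glmm(data)

    def test_formula_parsing(self):
        assert parse_formula("count ~ bodysize + (1|population)") is False
        assert parse_formula("count ~ bodysize + (1|population) + (1|obs)") is True
        with pytest.raises(ValueError):
            parse_formula("count ~ bodysize + (bodysize|population)")


class TestPearsonResiduals:
    def _dummy_fit(self, mu):
        mu = np.asarray(mu, dtype=float)
        return PoissonGLMMFit(
            intercept_hat=0.0, slope_hat=0.0, intercept_se=1.0, slope_se=1.0,
            sigma_alpha_hat=0.0, sigma_eps_hat=None,
            modes_population=np.zeros(1), modes_olre=None,
            fitted_means=mu, loglik_laplace=0.0, converged=True, n_obs=len(mu))

    def test_perfect_fit_zero_residuals(self):
        data = CountDataset(counts=np.array([2, 3]), covariate=np.zeros(2),
                            population=np.array([0, 0]))
        r = pearson_residuals(self._dummy_fit([2.0, 3.0]), data)
        assert np.allclose(r, 0.0)

    def test_hand_computed_values(self):
        data = CountDataset(counts=np.array([2, 0]), covariate=np.zeros(2),
                            population=np.array([0, 0]))
        r = pearson_residuals(self._dummy_fit([1.0, 1.0]), data)
        assert np.allclose(r, [1.0, -1.0])
        assert np.isclose(np.sum(r**2), 2.0)

    def test_well_specified_dispersion_near_one(self):
        """Mean Pearson SS / df over replicates approximates the chi-square
        expectation of 1 under a correctly specified model."""
        vals = []
        for rep in range(20):
            d = simulate(SimScenario(process="pure_poisson"), replicate_rng(21, 0, rep))
            fit = fit_poisson_glmm(d, include_olre=False)
            r = pearson_residuals(fit, d)
            vals.append(np.sum(r**2) / (d.n_obs - 2 - 1))
        assert abs(np.mean(vals) - 1.0) < 0.15


class TestRecoveryAndInvariances:
    def test_olre_recovers_slope_and_intercept(self):
        """At mild noise the OLRE model is unbiased for all parameters."""
        slopes, intercepts, sigmas = [], [], []
        for rep in range(40):
            d = simulate(SimScenario(process="noise", grid_value=0.1),
                         replicate_rng(33, 0, rep))
            f = fit_poisson_glmm(d, include_olre=True)
            slopes.append(f.slope_hat)
            intercepts.append(f.intercept_hat)
            sigmas.append(f.sigma_alpha_hat)
        n = len(slopes)
        assert abs(np.mean(slopes) - 0.1) < 3 * np.std(slopes) / np.sqrt(n)
        assert abs(np.mean(intercepts) + 0.5) < 3 * np.std(intercepts) / np.sqrt(n)
        assert 0.40 < np.mean(sigmas) < 0.55

    def test_se_monotonicity_olre_vs_naive(self, noise_fits_mid):
        naive, olre = noise_fits_mid
        assert olre.sigma_eps_hat > 0
        assert olre.slope_se >= naive.slope_se

    def test_row_permutation_invariance(self, noise_data_mid):
        d = noise_data_mid
        perm = np.random.default_rng(0).permutation(d.n_obs)
        d2 = CountDataset(counts=d.counts[perm], covariate=d.covariate[perm],
                          population=d.population[perm])
        f1 = fit_poisson_glmm(d, include_olre=False)
        f2 = fit_poisson_glmm(d2, include_olre=False)
        assert abs(f1.intercept_hat - f2.intercept_hat) < 1e-4
        assert abs(f1.slope_hat - f2.slope_hat) < 1e-5
        assert abs(f1.sigma_alpha_hat - f2.sigma_alpha_hat) < 1e-4

    def test_fit_contract_fields(self, noise_fits_mid):
        naive, olre = noise_fits_mid
        for f in (naive, olre):
            assert f.converged
            assert np.all(f.fitted_means > 0)
            assert f.intercept_se > 0 and f.slope_se > 0
        assert naive.sigma_eps_hat is None and naive.n_varparams == 1
        assert olre.sigma_eps_hat is not None and olre.n_varparams == 2
        assert len(olre.conditional_modes) == olre.n_obs + 10


class TestSimulateFromFit:
    def _null_fit(self, n):
        return PoissonGLMMFit(
            intercept_hat=0.0, slope_hat=0.0, intercept_se=1.0, slope_se=1.0,
            sigma_alpha_hat=0.0, sigma_eps_hat=None,
            modes_population=np.zeros(1), modes_olre=None,
            fitted_means=np.ones(n), loglik_laplace=0.0, converged=True, n_obs=n)

    def test_no_random_structure_gives_unit_poisson(self, rng):
        n = 50_000
        data = CountDataset(counts=np.zeros(n, dtype=int), covariate=np.zeros(n),
                            population=np.zeros(n, dtype=int))
        y = simulate_from_fit(self._null_fit(n), data, rng)
        assert abs(y.mean() - 1.0) < 0.02
        assert abs(y.var() - 1.0) < 0.03

    def test_lognormal_mixture_mean_identity(self, noise_fits_mid, noise_data_mid, rng):
        """Mean of repeated simulations at observation i approaches
        exp(x_i' beta + sigma_total^2 / 2)."""
        _, olre = noise_fits_mid
        sims = np.array([simulate_from_fit(olre, noise_data_mid, rng) for _ in range(1000)])
        var_tot = olre.sigma_alpha_hat**2 + olre.sigma_eps_hat**2
        for i in (0, 123, 499):
            expected = np.exp(olre.intercept_hat + olre.slope_hat * noise_data_mid.covariate[i]
                              + var_tot / 2)
            mc_se = sims[:, i].std(ddof=1) / np.sqrt(1000)
            assert abs(sims[:, i].mean() - expected) < 3 * mc_se + 0.02 * expected

    def test_naive_fit_understates_overdispersed_variance(self, rng):
        d = simulate(SimScenario(process="noise", grid_value=1.0), replicate_rng(8, 0, 0))
        fit = fit_poisson_glmm(d, include_olre=False)
        sim_vars = [simulate_from_fit(fit, d, rng).var() for _ in range(20)]
        assert np.mean(sim_vars) < 0.5 * d.counts.var()
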