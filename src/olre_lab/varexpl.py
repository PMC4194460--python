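"""Variance decomposition and marginal/conditional r-squared for Poisson GLMMs.

Implements the mixed-model r-squared of Nakagawa & Schielzeth for the
Poisson log link.  The latent-scale variance is decomposed into

* ``var_fixed`` — the variance of the fixed-effect linear predictor
  (slope x covariate; the intercept contributes no variance),
* ``var_random`` — the summed random-intercept variances
  (``sigma_alpha^2`` plus, when the model has one, the OLRE variance
  ``sigma_eps^2``),
* ``var_residual`` — the distribution-specific variance of a log-link
  Poisson model, ``ln(1 + 1/lambda_bar)`` from the lognormal approximation,
  where ``lambda_bar`` is the model-implied mean count.

``lambda_bar`` is computed as ``exp(eta_bar + var_random/2)`` with
``eta_bar`` the mean fixed-effect linear predictor (intercept plus slope
times the covariate mean); the half-variance term is the lognormal mean
correction and can be switched off.

Marginal r2 = fixed / total; conditional r2 = (fixed + random) / total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pglmm import PoissonGLMMFit
from .synthcounts import CountDataset

__all__ = ["VarianceComponents", "R2Result", "variance_components", "r_squared"]


@dataclass
class VarianceComponents:
    """Latent-scale variance decomposition of a fitted Poisson GLMM."""

    var_fixed: float
    var_random: float
    var_residual: float

    @property
    def total(self) -> float:
        return self.var_fixed + self.var_random + self.var_residual

    def to_dict(self) -> dict:
        return {
            "var_fixed": self.var_fixed,
            "var_random": self.var_random,
            "var_residual": self.var_residual,
        }


@dataclass
class R2Result:
    """Marginal and conditional r-squared; conditional >= marginal always."""

    marginal: float
    conditional: float

    def to_dict(self) -> dict:
        return {"marginal_r2": self.marginal, "conditional_r2": self.conditional}


def variance_components(fit: PoissonGLMMFit, data: CountDataset,
                        half_variance_correction: bool = True) -> VarianceComponents:
    """Decompose a fitted model's variance into fixed, random, residual parts.

    Parameters
    ----------
    fit
        A converged Poisson GLMM fit.
    data
        The dataset the model was fitted to (supplies the covariate).
    half_variance_correction
        Include the ``+ var_random/2`` lognormal mean correction in
        ``lambda_bar``.  On by default.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; variance components undefined")
    x = np.asarray(data.covariate, dtype=float)
    var_fixed = float(np.var(fit.slope_hat * x, ddof=1))
    var_random = fit.sigma_alpha_hat ** 2
    if fit.include_olre:
        var_random += fit.sigma_eps_hat ** 2

    eta_bar = fit.intercept_hat + fit.slope_hat * x.mean()
    if half_variance_correction:
        eta_bar = eta_bar + 0.5 * var_random
    if not np.isfinite(eta_bar) or abs(eta_bar) > 700:
        raise FloatingPointError(f"lambda_bar over/underflow at eta_bar={eta_bar!r}")
    lam_bar = np.exp(eta_bar)
    if lam_bar <= 0 or not np.isfinite(lam_bar):
        raise FloatingPointError("lambda_bar is degenerate; residual variance undefined")
    var_residual = float(np.log1p(1.0 / lam_bar))
    return VarianceComponents(var_fixed=var_fixed, var_random=float(var_random),
                              var_residual=var_residual)


def r_squared(components: VarianceComponents) -> R2Result:
    """Marginal and conditional r-squared from variance components."""
    total = components.total
    if total <= 0:
        raise ValueError("total variance is zero; r-squared undefined")
    return R2Result(
        marginal=components.var_fixed / total,
        conditional=(components.var_fixed + components.var_random) / total,
    )
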