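"""Overdispersion diagnostics for fitted Poisson mixed models.

Two complementary diagnostics:

* a point dispersion statistic — the sum of squared Pearson residuals over
  the residual degrees of freedom, with an upper-tail chi-square p-value
  (values > 1 indicate overdispersion);
* a parametric-bootstrap version — the response is re-simulated from the
  fitted model's estimates and distributional assumptions, the model refitted,
  and the original Pearson sum-of-squares divided by each bootstrap
  sum-of-squares.  The mean of these ratios estimates the same dispersion
  parameter without needing a residual-df convention, and the ratio
  distribution yields a percentile confidence interval.

Residual degrees of freedom default to ``n - n_fixed - n_varparams``
(one df charged per random term); the alternative convention that charges
one df per random-effect *level* is available via ``df_mode="levels"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .pglmm import PoissonGLMMFit, fit_poisson_glmm, pearson_residuals, simulate_from_fit
from .synthcounts import CountDataset

__all__ = ["DispersionResult", "dispersion_point", "dispersion_bootstrap"]


@dataclass
class DispersionResult:
    """Dispersion statistic with optional parametric-bootstrap distribution."""

    pearson_ss: float
    residual_df: int
    point_dispersion: float
    chisq_p: float
    boot_ratios: Optional[np.ndarray] = None
    boot_mean: Optional[float] = None
    boot_ci_low: Optional[float] = None
    boot_ci_high: Optional[float] = None
    n_boot_failed: int = 0

    def to_dict(self) -> dict:
        d = {
            "pearson_ss": self.pearson_ss,
            "residual_df": self.residual_df,
            "point_dispersion": self.point_dispersion,
            "chisq_p": self.chisq_p,
        }
        if self.boot_ratios is not None:
            d.update(
                boot_mean=self.boot_mean,
                boot_ci_low=self.boot_ci_low,
                boot_ci_high=self.boot_ci_high,
                n_boot=len(self.boot_ratios),
                n_boot_failed=self.n_boot_failed,
            )
        return d


def _residual_df(fit: PoissonGLMMFit, df_mode: str) -> int:
    if df_mode == "per_term":
        df = fit.n_obs - fit.n_fixed - fit.n_varparams
    elif df_mode == "levels":
        n_levels = len(fit.modes_population) + (len(fit.modes_olre) if fit.modes_olre is not None else 0)
        df = fit.n_obs - fit.n_fixed - n_levels
    else:
        raise ValueError("df_mode must be 'per_term' or 'levels'")
    if df <= 0:
        raise ValueError(f"non-positive residual degrees of freedom ({df})")
    return int(df)


def dispersion_point(fit: PoissonGLMMFit, data: CountDataset,
                     df_mode: str = "per_term") -> DispersionResult:
    """Pearson dispersion statistic and chi-square overdispersion test.

    The statistic is ``sum(r_i^2) / residual_df`` with conditional Pearson
    residuals; under a correctly specified Poisson model the sum approximates
    a chi-square with ``residual_df`` degrees of freedom, giving the reported
    upper-tail p-value.
    """
    r = pearson_residuals(fit, data)
    ss = float(np.sum(r ** 2))
    df = _residual_df(fit, df_mode)
    return DispersionResult(
        pearson_ss=ss,
        residual_df=df,
        point_dispersion=ss / df,
        chisq_p=float(stats.chi2.sf(ss, df)),
    )


def dispersion_bootstrap(fit: PoissonGLMMFit, data: CountDataset, n_boot: int = 100,
                         rng: Optional[np.random.Generator] = None,
                         df_mode: str = "per_term") -> DispersionResult:
    """Parametric-bootstrap dispersion parameter with a 95% percentile CI.

    Each replicate simulates a fresh response from the fitted model (new
    random-effect draws, Poisson sampling), refits the same model
    specification, and records that refit's Pearson sum of squares.  The
    returned ratios are original SS / bootstrap SS; their mean is the
    bootstrap dispersion estimate.  Raises if more than 20% of refits fail.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng() if rng is None else rng
    base = dispersion_point(fit, data, df_mode)

    ratios = []
    failed = 0
    start = (fit.sigma_alpha_hat or 0.3, fit.sigma_eps_hat if fit.include_olre else None)
    for _ in range(n_boot):
        y_new = simulate_from_fit(fit, data, rng)
        boot_data = CountDataset(counts=y_new, covariate=data.covariate,
                                 population=data.population)
        try:
            refit = fit_poisson_glmm(boot_data, include_olre=fit.include_olre,
                                     start_sigmas=start)
            if not refit.converged:
                failed += 1
                continue
            ss_b = float(np.sum(pearson_residuals(refit, boot_data) ** 2))
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            failed += 1
            continue
        ratios.append(base.pearson_ss / ss_b)

    if failed > 0.2 * n_boot:
        raise RuntimeError(f"parametric bootstrap failed in {failed}/{n_boot} replicates")

    ratios = np.asarray(ratios)
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return DispersionResult(
        pearson_ss=base.pearson_ss,
        residual_df=base.residual_df,
        point_dispersion=base.point_dispersion,
        chisq_p=base.chisq_p,
        boot_ratios=ratios,
        boot_mean=float(ratios.mean()),
        boot_ci_low=float(lo),
        boot_ci_high=float(hi),
        n_boot_failed=failed,
    )
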