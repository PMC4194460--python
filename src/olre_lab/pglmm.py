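"""Poisson log-link mixed models with a population intercept and optional OLRE.

Fits the two model forms at the centre of the overdispersion study::

    count ~ bodysize + (1|population)            # "naive"
    count ~ bodysize + (1|population) + (1|obs)  # "OLRE"

by maximum likelihood under the Laplace approximation.  The fixed effects and
all random-effect modes are profiled out by penalized iteratively reweighted
least squares (PIRLS); the outer optimization runs over the random-effect
standard deviations on the log scale.  Because every observation belongs to
exactly one population and owns at most one OLRE level, the penalized normal
equations can be solved exactly in O(n) per iteration: the OLRE block is
diagonal, and after eliminating it the population block is diagonal too, so
no general sparse factorization is needed.

Wald standard errors for the fixed effects come from the 2x2 profiled
information matrix at the optimum (the Schur complement of the joint Hessian
onto the fixed effects), with the variance parameters held at their
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln

from .synthcounts import CountDataset

__all__ = ["PoissonGLMMFit", "fit_poisson_glmm", "pearson_residuals", "simulate_from_fit", "parse_formula"]

# Variance parameters are kept off exact zero for numerical stability; SDs
# estimated below _SD_ZERO_TOL are reported as 0 (boundary estimates).
_SD_FLOOR = 1e-6
_SD_ZERO_TOL = 1e-4
_ETA_CLIP = 30.0


@dataclass
class PoissonGLMMFit:
    """A fitted Poisson mixed model (log link)."""

    intercept_hat: float
    slope_hat: float
    intercept_se: float
    slope_se: float
    sigma_alpha_hat: float
    sigma_eps_hat: Optional[float]  # present iff the OLRE term was requested
    modes_population: np.ndarray
    modes_olre: Optional[np.ndarray]
    fitted_means: np.ndarray
    loglik_laplace: float
    converged: bool
    n_obs: int
    n_fixed: int = 2
    n_varparams: int = 1
    message: str = ""

    @property
    def include_olre(self) -> bool:
        return self.sigma_eps_hat is not None

    @property
    def conditional_modes(self) -> np.ndarray:
        """All random-effect conditional modes, population levels first."""
        if self.modes_olre is None:
            return self.modes_population
        return np.concatenate([self.modes_population, self.modes_olre])

    def to_dict(self) -> dict:
        return {
            "intercept_hat": self.intercept_hat,
            "slope_hat": self.slope_hat,
            "intercept_se": self.intercept_se,
            "slope_se": self.slope_se,
            "sigma_alpha_hat": self.sigma_alpha_hat,
            "sigma_eps_hat": self.sigma_eps_hat,
            "loglik_laplace": self.loglik_laplace,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }


def parse_formula(formula: str) -> bool:
    """Parse the minimal model formula; returns whether an OLRE is requested.

    Accepted forms are ``count ~ bodysize + (1|population)`` optionally
    followed by ``+ (1|obs)`` (whitespace-insensitive).
    """
    compact = formula.replace(" ", "").lower()
    base = "count~bodysize+(1|population)"
    if compact == base:
        return False
    if compact == base + "+(1|obs)":
        return True
    raise ValueError(
        "unsupported formula; expected 'count ~ bodysize + (1|population) [+ (1|obs)]'"
    )


class _PIRLSWorkspace:
    """Cached per-dataset arrays plus warm-start state across outer steps."""

    def __init__(self, y: np.ndarray, x: np.ndarray, pop: np.ndarray, n_pop: int):
        self.y = y.astype(float)
        self.x = x
        self.pop = pop
        self.n_pop = n_pop
        self.n = len(y)
        self.lgamma_y1 = gammaln(self.y + 1.0)
        # warm-start state (beta0, beta1, u, e)
        self.beta = None
        self.u = None
        self.e = None

    def reset_start(self, beta: np.ndarray) -> None:
        self.beta = beta.copy()
        self.u = np.zeros(self.n_pop)
        self.e = np.zeros(self.n)


def _penalized_deviance(ws: _PIRLSWorkspace, eta, mu, u, e, inv_va, inv_ve) -> float:
    pois = np.sum(ws.y * eta - mu)
    pen = 0.5 * inv_va * np.dot(u, u)
    if inv_ve is not None:
        pen += 0.5 * inv_ve * np.dot(e, e)
    return -(pois) + pen


def _pirls(ws: _PIRLSWorkspace, sigma_alpha: float, sigma_eps: Optional[float],
           max_iter: int = 80, tol: float = 1e-10):
    """Joint penalized-likelihood mode over (beta, u, e) at fixed SDs.

    Returns (beta, u, e, mu, info2x2, converged).  Each iteration solves the
    penalized weighted least-squares problem exactly: the OLRE coordinates
    are eliminated first (diagonal), which rescales the working weights to
    ``w / (1 + w*sigma_eps^2)``; the population coordinates are then
    eliminated (diagonal after the first elimination because populations
    partition the observations), leaving a 2x2 solve for the fixed effects.
    """
    y, x, pop, n_pop = ws.y, ws.x, ws.pop, ws.n_pop
    inv_va = 1.0 / (sigma_alpha ** 2)
    has_olre = sigma_eps is not None
    ve = sigma_eps ** 2 if has_olre else 0.0
    inv_ve = (1.0 / ve) if has_olre else None

    beta = ws.beta.copy()
    u = ws.u.copy()
    e = ws.e.copy()

    eta = beta[0] + beta[1] * x + u[pop] + (e if has_olre else 0.0)
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    q_old = _penalized_deviance(ws, eta, mu, u, e, inv_va, inv_ve)

    A = np.empty((2, 2))
    converged = False
    for _ in range(max_iter):
        w = np.maximum(mu, 1e-10)
        z = eta + (y - mu) / w
        if has_olre:
            wt = w / (1.0 + w * ve)
        else:
            wt = w
        wx = wt * x
        # population-level accumulations
        sw = np.bincount(pop, weights=wt, minlength=n_pop)
        swx = np.bincount(pop, weights=wx, minlength=n_pop)
        swz = np.bincount(pop, weights=wt * z, minlength=n_pop)
        swxz = np.bincount(pop, weights=wx * z, minlength=n_pop)
        swxx = np.bincount(pop, weights=wx * x, minlength=n_pop)
        denom = sw + inv_va
        # 2x2 profiled system for beta
        A[0, 0] = sw.sum() - np.sum(sw * sw / denom)
        A[0, 1] = A[1, 0] = swx.sum() - np.sum(sw * swx / denom)
        A[1, 1] = swxx.sum() - np.sum(swx * swx / denom)
        b0 = swz.sum() - np.sum(sw * swz / denom)
        b1 = swxz.sum() - np.sum(swx * swz / denom)
        try:
            beta_new = np.linalg.solve(A, np.array([b0, b1]))
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(A, np.array([b0, b1]), rcond=None)
        u_new = (swz - sw * beta_new[0] - swx * beta_new[1]) / denom
        r = z - beta_new[0] - beta_new[1] * x - u_new[pop]
        e_new = (r * w * ve / (1.0 + w * ve)) if has_olre else np.zeros(ws.n)

        # step-halving on the penalized deviance
        step = 1.0
        for _half in range(12):
            bb = beta + step * (beta_new - beta)
            uu = u + step * (u_new - u)
            ee = e + step * (e_new - e)
            eta_t = np.clip(bb[0] + bb[1] * x + uu[pop] + (ee if has_olre else 0.0), -_ETA_CLIP, _ETA_CLIP)
            mu_t = np.exp(eta_t)
            q_new = _penalized_deviance(ws, eta_t, mu_t, uu, ee, inv_va, inv_ve)
            if q_new <= q_old + 1e-12 * (1.0 + abs(q_old)):
                break
            step *= 0.5
        beta, u, e, eta, mu = bb, uu, ee, eta_t, mu_t
        if abs(q_old - q_new) < tol * (1.0 + abs(q_old)):
            converged = True
            q_old = q_new
            break
        q_old = q_new

    ws.beta, ws.u, ws.e = beta, u, e
    return beta, u, e, mu, A, converged


def _laplace_terms(ws: _PIRLSWorkspace, u, e, mu, sigma_alpha: float, sigma_eps: Optional[float]) -> float:
    """Laplace log marginal likelihood given the conditional modes."""
    y, pop, n_pop = ws.y, ws.pop, ws.n_pop
    va = sigma_alpha ** 2
    eta = np.log(mu)
    ll = np.sum(y * eta - mu - ws.lgamma_y1) - 0.5 * np.dot(u, u) / va
    if sigma_eps is not None:
        ve = sigma_eps ** 2
        ll -= 0.5 * np.dot(e, e) / ve
        # log-det of the random-effects Hessian folded with the prior
        # normalization: OLRE block is diagonal; the population block is
        # diagonal after the OLRE Schur complement with entries sum_j w_tilde.
        wt = mu / (1.0 + mu * ve)
        ll -= 0.5 * np.sum(np.log1p(mu * ve))
        sw = np.bincount(pop, weights=wt, minlength=n_pop)
        ll -= 0.5 * np.sum(np.log1p(va * sw))
    else:
        sw = np.bincount(pop, weights=mu, minlength=n_pop)
        ll -= 0.5 * np.sum(np.log1p(va * sw))
    return ll


def _laplace_loglik(ws: _PIRLSWorkspace, sigma_alpha: float, sigma_eps: Optional[float]):
    """Laplace log likelihood with the fixed effects profiled out in PIRLS."""
    beta, u, e, mu, A, ok = _pirls(ws, sigma_alpha, sigma_eps)
    ll = _laplace_terms(ws, u, e, mu, sigma_alpha, sigma_eps)
    return ll, beta, u, e, mu, A, ok


def _pirls_modes(ws: _PIRLSWorkspace, beta: np.ndarray, sigma_alpha: float,
                 sigma_eps: Optional[float], max_iter: int = 60, tol: float = 1e-11):
    """Conditional modes (u, e) at fixed beta and fixed SDs."""
    y, x, pop, n_pop = ws.y, ws.x, ws.pop, ws.n_pop
    inv_va = 1.0 / (sigma_alpha ** 2)
    has_olre = sigma_eps is not None
    ve = sigma_eps ** 2 if has_olre else 0.0
    inv_ve = (1.0 / ve) if has_olre else None
    u = ws.u.copy()
    e = ws.e.copy()
    off = beta[0] + beta[1] * x
    eta = np.clip(off + u[pop] + (e if has_olre else 0.0), -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    q_old = _penalized_deviance(ws, eta, mu, u, e, inv_va, inv_ve)
    for _ in range(max_iter):
        w = np.maximum(mu, 1e-10)
        z = eta + (y - mu) / w - off
        wt = w / (1.0 + w * ve) if has_olre else w
        sw = np.bincount(pop, weights=wt, minlength=n_pop)
        swz = np.bincount(pop, weights=wt * z, minlength=n_pop)
        u_new = swz / (sw + inv_va)
        r = z - u_new[pop]
        e_new = (r * w * ve / (1.0 + w * ve)) if has_olre else np.zeros(ws.n)
        step = 1.0
        for _half in range(12):
            uu = u + step * (u_new - u)
            ee = e + step * (e_new - e)
            eta_t = np.clip(off + uu[pop] + (ee if has_olre else 0.0), -_ETA_CLIP, _ETA_CLIP)
            mu_t = np.exp(eta_t)
            q_new = _penalized_deviance(ws, eta_t, mu_t, uu, ee, inv_va, inv_ve)
            if q_new <= q_old + 1e-12 * (1.0 + abs(q_old)):
                break
            step *= 0.5
        u, e, eta, mu = uu, ee, eta_t, mu_t
        if abs(q_old - q_new) < tol * (1.0 + abs(q_old)):
            q_old = q_new
            break
        q_old = q_new
    ws.u, ws.e = u, e
    return u, e, mu


def _profiled_information(ws: _PIRLSWorkspace, mu: np.ndarray, sigma_alpha: float,
                          sigma_eps: Optional[float]) -> np.ndarray:
    """2x2 fixed-effect information with the random effects profiled out."""
    x, pop, n_pop = ws.x, ws.pop, ws.n_pop
    inv_va = 1.0 / (sigma_alpha ** 2)
    w = np.maximum(mu, 1e-10)
    wt = w / (1.0 + w * sigma_eps ** 2) if sigma_eps is not None else w
    wx = wt * x
    sw = np.bincount(pop, weights=wt, minlength=n_pop)
    swx = np.bincount(pop, weights=wx, minlength=n_pop)
    swxx = np.bincount(pop, weights=wx * x, minlength=n_pop)
    denom = sw + inv_va
    A = np.empty((2, 2))
    A[0, 0] = sw.sum() - np.sum(sw * sw / denom)
    A[0, 1] = A[1, 0] = swx.sum() - np.sum(sw * swx / denom)
    A[1, 1] = swxx.sum() - np.sum(swx * swx / denom)
    return A


def fit_poisson_glmm(data: CountDataset, include_olre: bool = False,
                     formula: Optional[str] = None,
                     start_sigmas: Optional[tuple] = None,
                     max_restarts: int = 3) -> PoissonGLMMFit:
    """Fit a Poisson log-link GLMM by Laplace-approximate maximum likelihood.

    Parameters
    ----------
    data
        Counts, covariate and population labels.
    include_olre
        Add an observation-level random intercept (one level per row),
        turning the model into a Poisson-lognormal fit.
    formula
        Optional formula string overriding ``include_olre``; see
        :func:`parse_formula`.
    start_sigmas
        Optional (sigma_alpha, sigma_eps) starting values, e.g. to warm-start
        bootstrap refits from the original estimates.
    max_restarts
        Jittered restarts if the outer optimizer reports failure.
    """
    if formula is not None:
        include_olre = parse_formula(formula)
    y = np.asarray(data.counts)
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    x = np.asarray(data.covariate, dtype=float)
    pop = np.asarray(data.population)
    n_pop = int(pop.max()) + 1
    ws = _PIRLSWorkspace(y, x, pop, n_pop)

    # Fixed-effect starts from a plain Poisson GLM ignoring random terms
    # (two IRLS-free Newton passes are enough for a starting point).
    beta0 = np.array([np.log(max(y.mean(), 0.1)), 0.0])
    for _ in range(8):
        eta = np.clip(beta0[0] + beta0[1] * x, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        z = eta + (y - mu) / np.maximum(mu, 1e-10)
        W = np.maximum(mu, 1e-10)
        X = np.column_stack([np.ones_like(x), x])
        XtW = X.T * W
        try:
            beta0 = np.linalg.solve(XtW @ X, XtW @ z)
        except np.linalg.LinAlgError:
            beta0, *_ = np.linalg.lstsq(XtW @ X, XtW @ z, rcond=None)
            break
    ws.reset_start(beta0)

    log_floor = np.log(_SD_FLOOR)
    log_ceil = np.log(10.0)

    if start_sigmas is not None:
        sa0 = float(np.clip(start_sigmas[0], _SD_FLOOR, 10.0))
        se0 = float(np.clip(start_sigmas[1], _SD_FLOOR, 10.0)) if (include_olre and start_sigmas[1]) else 0.3
    else:
        sa0 = se0 = 0.3

    converged = False
    message = ""
    rng_jitter = np.random.default_rng(0)

    # Stage 1: optimize the SDs with the fixed effects profiled inside PIRLS.
    # This lands very close to the optimum and is cheap; stage 2 below then
    # optimizes the fixed effects and SDs jointly (PIRLS over the random
    # effects only), which matters for the OLRE model because the Laplace
    # log-determinant depends on the fixed effects through the n
    # observation-level curvature terms.
    if include_olre:
        def objective1(theta):
            sa = np.exp(np.clip(theta[0], log_floor, log_ceil))
            se = np.exp(np.clip(theta[1], log_floor, log_ceil))
            ll, *_ = _laplace_loglik(ws, sa, se)
            return -ll

        theta0 = np.array([np.log(sa0), np.log(se0)])
        res1 = minimize(objective1, theta0, method="Nelder-Mead",
                        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
        sigma_alpha = float(np.exp(np.clip(res1.x[0], log_floor, log_ceil)))
        sigma_eps = float(np.exp(np.clip(res1.x[1], log_floor, log_ceil)))
    else:
        def objective1(t):
            ll, *_ = _laplace_loglik(ws, np.exp(t), None)
            return -ll

        res1 = minimize_scalar(objective1, bounds=(log_floor, log_ceil), method="bounded",
                               options={"xatol": 1e-6})
        sigma_alpha = float(np.exp(res1.x))
        sigma_eps = None
    _, beta, u, e, mu, _, _ = _laplace_loglik(ws, sigma_alpha, sigma_eps)

    # Stage 2: joint (beta, log sigma) maximization of the Laplace objective.
    def objective2(params):
        b = params[:2]
        sa = np.exp(np.clip(params[2], log_floor, log_ceil))
        se = np.exp(np.clip(params[3], log_floor, log_ceil)) if include_olre else None
        uu, ee, mm = _pirls_modes(ws, b, sa, se)
        return -_laplace_terms(ws, uu, ee, mm, sa, se)

    p0 = np.concatenate([beta, [np.log(max(sigma_alpha, _SD_FLOOR))]])
    if include_olre:
        p0 = np.append(p0, np.log(max(sigma_eps, _SD_FLOOR)))
    for attempt in range(max_restarts + 1):
        res = minimize(objective2, p0, method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-8,
                                "maxiter": 2000, "maxfev": 2000})
        if res.success:
            converged = True
            break
        message = str(res.message)
        p0 = res.x + rng_jitter.normal(0.0, 0.05, size=len(res.x))

    beta = res.x[:2]
    sigma_alpha = float(np.exp(np.clip(res.x[2], log_floor, log_ceil)))
    if include_olre:
        sigma_eps = float(np.exp(np.clip(res.x[3], log_floor, log_ceil)))
    u, e, mu = _pirls_modes(ws, beta, sigma_alpha, sigma_eps)
    ll = _laplace_terms(ws, u, e, mu, sigma_alpha, sigma_eps)
    if not converged and not message:
        message = "outer optimizer failed to converge"

    A = _profiled_information(ws, mu, sigma_alpha, sigma_eps)
    try:
        vcov = np.linalg.inv(A)
        ses = np.sqrt(np.maximum(np.diag(vcov), 0.0))
    except np.linalg.LinAlgError:
        ses = np.array([np.nan, np.nan])
        converged = False
        message = "singular fixed-effect information"

    sa_rep = 0.0 if sigma_alpha < _SD_ZERO_TOL else sigma_alpha
    if include_olre:
        se_rep = 0.0 if sigma_eps < _SD_ZERO_TOL else sigma_eps
    else:
        se_rep = None

    return PoissonGLMMFit(
        intercept_hat=float(beta[0]),
        slope_hat=float(beta[1]),
        intercept_se=float(ses[0]),
        slope_se=float(ses[1]),
        sigma_alpha_hat=float(sa_rep),
        sigma_eps_hat=se_rep,
        modes_population=u.copy(),
        modes_olre=e.copy() if include_olre else None,
        fitted_means=mu.copy(),
        loglik_laplace=float(ll),
        converged=converged,
        n_obs=ws.n,
        n_fixed=2,
        n_varparams=2 if include_olre else 1,
        message=message,
    )


def pearson_residuals(fit: PoissonGLMMFit, data: CountDataset) -> np.ndarray:
    """Pearson residuals ``(y - mu_hat) / sqrt(mu_hat)``.

    ``mu_hat`` is the conditional fitted mean, i.e. it includes the
    conditional modes of every random effect in the model.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; residuals are not meaningful")
    mu = fit.fitted_means
    if np.any(mu <= 0):
        raise FloatingPointError("fitted means at zero; Pearson residuals undefined")
    return (np.asarray(data.counts, dtype=float) - mu) / np.sqrt(mu)


def simulate_from_fit(fit: PoissonGLMMFit, data: CountDataset, rng: np.random.Generator) -> np.ndarray:
    """Parametric-bootstrap response: resample every random effect, then counts.

    New population effects are drawn from ``N(0, sigma_alpha_hat)`` and (if
    the model has one) new OLRE values from ``N(0, sigma_eps_hat)``; counts
    are Poisson at the implied conditional means.  The covariate and the
    grouping structure are kept fixed.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; cannot simulate from it")
    pop = np.asarray(data.population)
    n_pop = int(pop.max()) + 1
    u_new = rng.normal(0.0, fit.sigma_alpha_hat, size=n_pop)
    eta = fit.intercept_hat + fit.slope_hat * np.asarray(data.covariate, dtype=float) + u_new[pop]
    if fit.include_olre:
        eta = eta + rng.normal(0.0, fit.sigma_eps_hat, size=fit.n_obs)
    return rng.poisson(np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP)))
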