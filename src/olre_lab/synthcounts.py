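"""Synthetic count-data generators for three overdispersion processes.

All generators share the same hierarchical skeleton: a hypothetical study in
which parasites are counted on ``n_per_pop`` individuals in each of ``n_pop``
populations, with a continuous body-size covariate.  Population intercepts
``alpha_j`` are normal on the log scale; the expected count for individual
``i`` in population ``j`` is ``exp(alpha_j + beta * x_i)``, perturbed by one
of three overdispersion mechanisms:

``noise``
    lognormal observation-level noise ``eps_i ~ N(0, sigma_eps)`` added to
    the linear predictor before Poisson sampling (a Poisson-lognormal
    process);
``zip``
    zero-inflation — each observation is independently replaced by zero with
    probability ``pi``;
``negbin``
    gamma-Poisson mixing with shape ``k``, giving negative binomial counts
    with ``var = mu + mu**2 / k``.

Every dataset carries a ``truth`` record with the realized latent draws so
that tests can reconstruct the exact Poisson means that were used.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Process",
    "SimScenario",
    "CountDataset",
    "draw_covariate",
    "simulate_noise",
    "simulate_zip",
    "simulate_negbin",
    "simulate_pure_poisson",
    "simulate",
    "replicate_rng",
    "write_dataset",
    "read_dataset",
]


class Process(str, Enum):
    """Which overdispersion-generating process a scenario uses."""

    NOISE = "noise"
    ZIP = "zip"
    NEGBIN = "negbin"
    PURE_POISSON = "pure_poisson"


# Shared constants of the simulation design: intercept mean/SD and slope on
# the log scale, 10 populations x 50 individuals, body size ~ N(30, 4).
DEFAULT_MU_ALPHA = -0.5
DEFAULT_SIGMA_ALPHA = 0.5
DEFAULT_BETA = 0.1
DEFAULT_N_POP = 10
DEFAULT_N_PER_POP = 50
DEFAULT_COV_MEAN = 30.0
DEFAULT_COV_SD = 4.0


@dataclass(frozen=True)
class SimScenario:
    """Full parameterization of one data-generating process.

    ``grid_value`` is the scenario-specific dial: ``sigma_eps`` for the noise
    process, the zero-inflation probability ``pi`` for ``zip``, the
    aggregation parameter ``k`` for ``negbin``; ignored for ``pure_poisson``.
    """

    process: Process
    grid_value: float = 0.0
    mu_alpha: float = DEFAULT_MU_ALPHA
    sigma_alpha: float = DEFAULT_SIGMA_ALPHA
    beta: float = DEFAULT_BETA
    n_pop: int = DEFAULT_N_POP
    n_per_pop: int = DEFAULT_N_PER_POP
    cov_mean: float = DEFAULT_COV_MEAN
    cov_sd: float = DEFAULT_COV_SD

    def __post_init__(self) -> None:
        proc = Process(self.process)
        object.__setattr__(self, "process", proc)
        if self.n_pop < 1 or self.n_per_pop < 1:
            raise ValueError("n_pop and n_per_pop must be positive integers")
        if self.sigma_alpha < 0:
            raise ValueError("sigma_alpha must be >= 0")
        if self.cov_sd < 0:
            raise ValueError("cov_sd must be >= 0")
        g = self.grid_value
        if proc is Process.NOISE and g < 0:
            raise ValueError("noise process requires sigma_eps >= 0")
        if proc is Process.ZIP and not (0.0 <= g <= 1.0):
            raise ValueError("zip process requires 0 <= pi <= 1")
        if proc is Process.NEGBIN and g <= 0:
            raise ValueError("negbin process requires k > 0")

    @property
    def n_obs(self) -> int:
        return self.n_pop * self.n_per_pop

    def to_dict(self) -> dict:
        return {
            "process": self.process.value,
            "grid_value": self.grid_value,
            "mu_alpha": self.mu_alpha,
            "sigma_alpha": self.sigma_alpha,
            "beta": self.beta,
            "n_pop": self.n_pop,
            "n_per_pop": self.n_per_pop,
            "cov_mean": self.cov_mean,
            "cov_sd": self.cov_sd,
        }


@dataclass
class Truth:
    """Realized latent quantities behind one simulated dataset."""

    scenario: SimScenario
    alpha: np.ndarray  # per-population intercepts, length n_pop
    eps: Optional[np.ndarray] = None  # per-observation noise (noise process)
    zero_mask: Optional[np.ndarray] = None  # bool, True where inflated to 0

    def poisson_means(self, covariate: np.ndarray, population: np.ndarray) -> np.ndarray:
        """Reconstruct the Poisson means used during sampling."""
        eta = self.alpha[population] + self.scenario.beta * covariate
        if self.eps is not None:
            eta = eta + self.eps
        return np.exp(eta)


@dataclass
class CountDataset:
    """One simulated (or user-supplied) count dataset.

    ``population`` is a zero-based integer code of length n; ``truth`` is
    present only for simulated data.
    """

    counts: np.ndarray
    covariate: np.ndarray
    population: np.ndarray
    truth: Optional[Truth] = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.covariate = np.asarray(self.covariate, dtype=float)
        self.population = np.asarray(self.population)
        if self.counts.ndim != 1 or self.covariate.ndim != 1 or self.population.ndim != 1:
            raise ValueError("counts, covariate and population must be 1-D")
        if not (len(self.counts) == len(self.covariate) == len(self.population)):
            raise ValueError("counts, covariate and population must share a length")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.floor(self.counts)) or np.any(self.counts < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        codes, _ = pd.factorize(self.population, sort=True)
        self.population = codes.astype(np.int64)

    @property
    def n_obs(self) -> int:
        return len(self.counts)

    @property
    def n_pop(self) -> int:
        return int(self.population.max()) + 1 if self.n_obs else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "count": self.counts,
                "bodysize": self.covariate,
                "population": self.population + 1,  # 1-based labels on disk
            }
        )


def replicate_rng(master_seed: int, scenario_index: int = 0, replicate_index: int = 0) -> np.random.Generator:
    """Seeded generator for one replicate of one scenario.

    The stream is derived as ``SeedSequence(master_seed,
    spawn_key=(scenario_index, replicate_index))``, so every replicate gets an
    independent, order-free stream: re-running replicate 57 alone yields the
    same data as running it inside a full grid sweep.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(int(scenario_index), int(replicate_index)))
    return np.random.default_rng(ss)


def draw_covariate(n: int, cov_mean: float = DEFAULT_COV_MEAN, cov_sd: float = DEFAULT_COV_SD,
                   rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Draw the body-size covariate: ``n`` iid normal values.

    Redrawn fresh for every simulated replicate, mirroring a study where each
    replicate samples new individuals.
    """
    if n < 1:
        raise ValueError("n must be a positive integer")
    if cov_sd < 0:
        raise ValueError("cov_sd must be >= 0")
    rng = np.random.default_rng() if rng is None else rng
    return rng.normal(cov_mean, cov_sd, size=int(n))


def _base_structure(scenario: SimScenario, rng: np.random.Generator):
    """Covariate, population index and per-population intercepts."""
    n = scenario.n_obs
    covariate = draw_covariate(n, scenario.cov_mean, scenario.cov_sd, rng)
    population = np.repeat(np.arange(scenario.n_pop), scenario.n_per_pop)
    alpha = rng.normal(scenario.mu_alpha, scenario.sigma_alpha, size=scenario.n_pop)
    return covariate, population, alpha


def simulate_noise(scenario: SimScenario, rng: np.random.Generator) -> CountDataset:
    """Poisson counts with lognormal observation-level noise in the mean.

    ``mu_ij = exp(alpha_j + beta * x_i + eps_i)`` with
    ``eps_i ~ N(0, sigma_eps)``; ``sigma_eps`` is ``scenario.grid_value``.
    """
    if scenario.process is not Process.NOISE:
        raise ValueError(f"scenario.process must be 'noise', got {scenario.process.value!r}")
    covariate, population, alpha = _base_structure(scenario, rng)
    eps = rng.normal(0.0, scenario.grid_value, size=scenario.n_obs)
    mu = np.exp(alpha[population] + scenario.beta * covariate + eps)
    counts = rng.poisson(mu)
    truth = Truth(scenario=scenario, alpha=alpha, eps=eps)
    return CountDataset(counts, covariate, population, truth)


def simulate_zip(scenario: SimScenario, rng: np.random.Generator) -> CountDataset:
    """Zero-inflated Poisson counts.

    Poisson counts with mean ``exp(alpha_j + beta * x_i)`` are generated
    first; each observation is then independently zeroed with probability
    ``pi = scenario.grid_value``.  The inflation mask is kept in ``truth``.
    """
    if scenario.process is not Process.ZIP:
        raise ValueError(f"scenario.process must be 'zip', got {scenario.process.value!r}")
    covariate, population, alpha = _base_structure(scenario, rng)
    mu = np.exp(alpha[population] + scenario.beta * covariate)
    counts = rng.poisson(mu)
    zero_mask = rng.random(scenario.n_obs) < scenario.grid_value
    counts = np.where(zero_mask, 0, counts)
    truth = Truth(scenario=scenario, alpha=alpha, zero_mask=zero_mask)
    return CountDataset(counts, covariate, population, truth)


def simulate_negbin(scenario: SimScenario, rng: np.random.Generator) -> CountDataset:
    """Negative binomial (aggregated) counts via a gamma-Poisson mixture.

    Each observation's Poisson rate is drawn from a Gamma with shape ``k``
    and mean ``mu_ij``, so the marginal counts are negative binomial with
    ``E(Y) = mu`` and ``var(Y) = mu + mu**2 / k``.
    """
    if scenario.process is not Process.NEGBIN:
        raise ValueError(f"scenario.process must be 'negbin', got {scenario.process.value!r}")
    k = scenario.grid_value
    covariate, population, alpha = _base_structure(scenario, rng)
    mu = np.exp(alpha[population] + scenario.beta * covariate)
    rate = rng.gamma(shape=k, scale=mu / k)
    counts = rng.poisson(rate)
    truth = Truth(scenario=scenario, alpha=alpha)
    return CountDataset(counts, covariate, population, truth)


def simulate_pure_poisson(scenario: SimScenario, rng: np.random.Generator) -> CountDataset:
    """Plain Poisson control: no noise, no inflation, no aggregation."""
    covariate, population, alpha = _base_structure(scenario, rng)
    mu = np.exp(alpha[population] + scenario.beta * covariate)
    counts = rng.poisson(mu)
    truth = Truth(scenario=scenario, alpha=alpha)
    return CountDataset(counts, covariate, population, truth)


_DISPATCH = {
    Process.NOISE: simulate_noise,
    Process.ZIP: simulate_zip,
    Process.NEGBIN: simulate_negbin,
    Process.PURE_POISSON: simulate_pure_poisson,
}


def simulate(scenario: SimScenario, rng: np.random.Generator) -> CountDataset:
    """Simulate one dataset under whichever process the scenario names."""
    return _DISPATCH[Process(scenario.process)](scenario, rng)


def write_dataset(data: CountDataset, path: str | Path, truth_sidecar: bool = False) -> None:
    """Write ``count,bodysize,population`` CSV, optionally a truth JSON sidecar."""
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    if truth_sidecar and data.truth is not None:
        sidecar = {
            "scenario": data.truth.scenario.to_dict(),
            "alpha": data.truth.alpha.tolist(),
            "eps": None if data.truth.eps is None else data.truth.eps.tolist(),
            "zero_mask": None if data.truth.zero_mask is None else data.truth.zero_mask.astype(int).tolist(),
        }
        path.with_suffix(path.suffix + ".truth.json").write_text(json.dumps(sidecar))


def read_dataset(path: str | Path) -> CountDataset:
    """Read a ``count,bodysize,population`` delimited table (comma or tab)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"count", "bodysize", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input table is missing columns: {sorted(missing)}")
    return CountDataset(
        counts=df["count"].to_numpy(),
        covariate=df["bodysize"].to_numpy(dtype=float),
        population=df["population"].to_numpy(),
    )
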