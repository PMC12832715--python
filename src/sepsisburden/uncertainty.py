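"""Probabilistic sensitivity analysis and pairwise rate comparison.

Two pieces of uncertainty machinery:

* **PSA** — a Monte Carlo simulation perturbing the two inputs of an
  expected-event computation (population size and the age-standardized
  rate), with a global sensitivity readout: the Spearman rank correlation
  of each input's draws against the output across iterations.  Default
  perturbation laws: event counts Poisson around the observed count (so the
  implied rate perturbation matches the Poisson variance model behind the
  rate engine) and population truncated-normal with a small coefficient of
  variation (projections carry small relative error).  Both are
  configurable.

* **Z-tests** — the difference between two standardized rates divided by
  the square root of the summed variances, with a two-sided normal p-value,
  expanded into symmetric pairwise matrices with the share of significant
  pairs.  Variances must be computed under a common (national) standard so
  they are comparable across geographies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .rate_engine import PER, RateEstimate

__all__ = [
    "PSASampling",
    "PSAResult",
    "psa",
    "z_test_pair",
    "ZTestMatrix",
    "pairwise_matrix",
    "spearman_rho",
]


class UncertaintyError(ValueError):
    pass


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float | None:
    """Spearman rank correlation; None for a zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


@dataclass(frozen=True)
class PSASampling:
    """Perturbation laws for the PSA inputs.

    ``rate_law`` is "poisson" (redraw event counts around the observed
    expectation, rate = 1e5 * events / population) or "normal"
    (truncated-normal around the observed rate with cv ``rate_cv``).
    """

    population_cv: float = 0.05
    rate_law: str = "poisson"
    rate_cv: float = 0.05

    def __post_init__(self):
        if self.rate_law not in ("poisson", "normal"):
            raise UncertaintyError(f"unknown rate law {self.rate_law!r}")
        if self.population_cv < 0 or self.rate_cv < 0:
            raise UncertaintyError("coefficients of variation must be non-negative")


@dataclass
class PSAResult:
    n_iter: int
    seed: int
    #: Spearman rho per input name; None where the input was degenerate.
    rho: dict = field(default_factory=dict)
    output_mean: float = 0.0
    output_sd: float = 0.0


def _truncnorm(rng: np.random.Generator, mean: np.ndarray, cv: float, size) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if cv == 0:
        return np.broadcast_to(mean, size).copy()
    sd = cv * mean
    a = (0.0 - mean) / sd
    u = rng.random(size)
    return stats.truncnorm.ppf(u, a=a, b=np.inf, loc=mean, scale=sd)


def psa(
    pop_cells: Sequence[float],
    rate_cells: Sequence[float],
    n_iter: int = 10_000,
    seed: int = 0,
    sampling: PSASampling | None = None,
) -> PSAResult:
    """Monte Carlo sensitivity analysis of expected event counts.

    Per iteration, population and rate are redrawn for every cell and the
    output is the total of expected events ``rate * population / 1e5``.
    The rank correlation of each input's per-iteration summary (total
    population draw; rate-driven expected events at observed population)
    against the output attributes output variation to its drivers.
    Identical seeds give bit-identical results.
    """
    if n_iter < 100:
        raise UncertaintyError(f"n_iter must be >= 100, got {n_iter}")
    sampling = sampling or PSASampling()
    pop = np.asarray(pop_cells, dtype=float)
    rate = np.asarray(rate_cells, dtype=float)
    if pop.shape != rate.shape:
        raise UncertaintyError("pop_cells and rate_cells must align")
    if np.any(pop <= 0) or np.any(rate < 0):
        raise UncertaintyError("populations must be positive and rates non-negative")

    rng = np.random.default_rng(seed)
    shape = (n_iter, pop.size)
    pop_draws = _truncnorm(rng, pop, sampling.population_cv, shape)
    if sampling.rate_law == "poisson":
        expected_counts = rate * pop / PER
        count_draws = rng.poisson(np.broadcast_to(expected_counts, shape)).astype(float)
        rate_draws = PER * count_draws / pop
    else:
        rate_draws = _truncnorm(rng, rate, sampling.rate_cv, shape)

    output = (rate_draws * pop_draws / PER).sum(axis=1)
    pop_input = pop_draws.sum(axis=1)
    rate_input = (rate_draws * pop / PER).sum(axis=1)

    return PSAResult(
        n_iter=n_iter,
        seed=seed,
        rho={
            "population": spearman_rho(pop_input, output),
            "rate": spearman_rho(rate_input, output),
        },
        output_mean=float(output.mean()),
        output_sd=float(output.std(ddof=1)),
    )


# ---------------------------------------------------------------------------
# Z-tests on rate differences
# ---------------------------------------------------------------------------

def z_test_pair(est1: RateEstimate, est2: RateEstimate) -> tuple[float, float]:
    """Z-test on the difference of two standardized rates.

    ``z = (asr1 - asr2) / sqrt(var1 + var2)`` with a two-sided normal
    p-value.  Two zero-variance estimates with equal rates give (0, 1);
    unequal rates with zero total variance are impossible under the Poisson
    variance model and raise.
    """
    var_sum = est1.variance + est2.variance
    diff = est1.asr - est2.asr
    if var_sum == 0:
        if diff == 0:
            return 0.0, 1.0
        raise UncertaintyError(
            "zero summed variance with unequal rates; variances are inconsistent with the counts"
        )
    z = diff / np.sqrt(var_sum)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), p


@dataclass
class ZTestMatrix:
    labels: list
    z: np.ndarray
    p: np.ndarray
    alpha: float
    significant_fraction_pct: float

    def p_frame(self):
        import pandas as pd

        return pd.DataFrame(self.p, index=self.labels, columns=self.labels)


def pairwise_matrix(
    estimates: Sequence[RateEstimate],
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    label_key: str = "geography",
) -> ZTestMatrix:
    """All-pairs Z-tests between geographies.

    Returns symmetric z and p matrices (diagonal NaN) plus the share of
    off-diagonal pairs significant at ``alpha`` — the "proportion of
    significant combinatorial differences".  No multiplicity adjustment is
    applied by default (apply Holm to ``p`` downstream if desired).
    """
    n = len(estimates)
    if n < 2:
        raise UncertaintyError("need at least two geographies")
    if labels is None:
        labels = [str(e.stratum.get(label_key, i)) for i, e in enumerate(estimates)]
    labels = list(labels)
    if len(set(labels)) != n:
        raise UncertaintyError("duplicate geography labels")
    z = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    n_sig = 0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            zij, pij = z_test_pair(estimates[i], estimates[j])
            z[i, j], z[j, i] = zij, -zij
            p[i, j] = p[j, i] = pij
            n_pairs += 1
            n_sig += pij < alpha
    return ZTestMatrix(
        labels=labels,
        z=z,
        p=p,
        alpha=alpha,
        significant_fraction_pct=100.0 * n_sig / n_pairs,
    )
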