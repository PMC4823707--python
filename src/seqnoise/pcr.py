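"""Galton–Watson branching-process model of PCR amplification.

Each cycle, every molecule is duplicated independently with probability
``efficiency`` (p), so a starting pool of m molecules evolves as a
branching process with per-molecule offspring 1 + Bernoulli(p).  The
amplified count of a single molecule converges (in the many-cycle limit,
after scaling) to an exponential-like law; the total over m independent
starting molecules is a sum of such terms and is well approximated by a
gamma distribution whose shape grows with m.  This is the mechanistic
reason sequencing counts of PCR-amplified libraries show quadratic
(gamma-type) rather than Poisson mean-variance scaling.

Implementation note: one binomial thinning per cycle on the aggregate
molecule count is distributionally identical to simulating every lineage
and costs O(cycles) per replicate instead of O(2^cycles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diagnostics import GammaParams, fit_gamma_moments, ks_gof_gamma

__all__ = [
    "PcrConfig",
    "AmplificationDraws",
    "GammaConvergenceReport",
    "simulate_amplification",
    "expected_yield",
    "simulate_sequencing_library",
    "gamma_convergence_report",
]


@dataclass(frozen=True)
class PcrConfig:
    """Branching-process parameters.

    initial_molecules:
        m >= 1, template copies of the molecule before amplification.
    cycles:
        n >= 0 PCR cycles.
    efficiency:
        p in [0, 1], per-cycle probability that a molecule is duplicated.
    n_replicates:
        number of independent amplification runs to draw.
    seed:
        seed for the replicate streams.
    """

    initial_molecules: int
    cycles: int
    efficiency: float
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_molecules < 1:
            raise ValueError("initial_molecules must be >= 1")
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class AmplificationDraws:
    """Final molecule counts of independent amplification replicates."""

    final_counts: np.ndarray
    config: PcrConfig


def _amplify(counts: np.ndarray, cycles: int, p: float, rng: np.random.Generator) -> np.ndarray:
    counts = counts.astype(np.int64, copy=True)
    for _ in range(cycles):
        counts += rng.binomial(counts, p)
    return counts


def simulate_amplification(cfg: PcrConfig) -> AmplificationDraws:
    """Draw ``n_replicates`` final molecule counts after ``cycles`` rounds.

    Every count lies in [m, m * 2^cycles]: amplification never loses
    molecules and at best doubles them each cycle.
    """
    rng = np.random.default_rng(cfg.seed)
    start = np.full(cfg.n_replicates, cfg.initial_molecules, dtype=np.int64)
    final = _amplify(start, cfg.cycles, cfg.efficiency, rng)
    return AmplificationDraws(final_counts=final, config=cfg)


def expected_yield(m: int, n: int, p: float) -> tuple[float, float]:
    """Analytic mean and variance of the final count.

    With per-cycle growth factor mu = 1 + p and per-molecule offspring
    variance sigma^2 = p(1 - p), the branching process gives

        mean     = m * mu^n
        variance = m * sigma^2 * mu^(n-1) * (mu^n - 1) / (mu - 1)

    Both p = 0 (no amplification) and p = 1 (deterministic doubling) are
    noise-free: variance 0.
    """
    mu = 1.0 + p
    mean = m * mu**n
    if p in (0.0, 1.0) or n == 0:
        return mean, 0.0
    sigma2 = p * (1.0 - p)
    variance = m * sigma2 * mu ** (n - 1) * (mu**n - 1.0) / (mu - 1.0)
    return mean, variance


def simulate_sequencing_library(
    abundances,
    cycles: int,
    efficiency: float,
    depth: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Amplify a vector of per-gene template abundances, optionally sample reads.

    Each gene's molecules amplify independently.  If ``depth`` is given,
    reads are drawn multinomially with probabilities proportional to the
    amplified molecule counts — the read-sampling stage of sequencing.  If
    ``depth`` is None the amplified molecule counts themselves are returned.
    """
    abundances = np.asarray(abundances, dtype=np.int64)
    if (abundances < 1).any():
        raise ValueError("abundances must be >= 1 molecule per gene")
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    amplified = _amplify(abundances, cycles, efficiency, rng)
    if depth is None:
        return amplified
    if depth < 0:
        raise ValueError("depth must be >= 0")
    probs = amplified / amplified.sum()
    return rng.multinomial(int(depth), probs)


@dataclass(frozen=True)
class GammaConvergenceReport:
    """How gamma-like the simulated amplification products are.

    Method-of-moments gamma fit to the final counts, a KS goodness-of-fit
    p-value against that fit, and empirical vs analytic first two moments.
    Degenerate configurations (p = 0 or 1: no stochasticity) carry no fit.
    """

    config: PcrConfig
    degenerate: bool
    empirical_mean: float
    empirical_variance: float
    analytic_mean: float
    analytic_variance: float
    gamma_fit: GammaParams | None = None
    ks_statistic: float | None = None
    ks_pvalue: float | None = None


def gamma_convergence_report(cfg: PcrConfig) -> GammaConvergenceReport:
    """Simulate, fit a gamma by moments, and KS-test the fit.

    Requires ``n_replicates >= 1000`` so the empirical distribution is
    informative.  The many-cycle gamma approximation is asymptotic; this
    report quantifies its adequacy at the given (m, n, p) instead of
    assuming it.
    """
    if cfg.n_replicates < 1000:
        raise ValueError("gamma convergence report needs n_replicates >= 1000")
    draws = simulate_amplification(cfg)
    counts = draws.final_counts.astype(float)
    a_mean, a_var = expected_yield(cfg.initial_molecules, cfg.cycles, cfg.efficiency)
    e_mean = float(counts.mean())
    e_var = float(counts.var(ddof=1))
    if cfg.efficiency in (0.0, 1.0) or cfg.cycles == 0:
        return GammaConvergenceReport(
            config=cfg, degenerate=True,
            empirical_mean=e_mean, empirical_variance=e_var,
            analytic_mean=a_mean, analytic_variance=a_var,
        )
    params = fit_gamma_moments(counts)
    ks = ks_gof_gamma(counts)
    return GammaConvergenceReport(
        config=cfg, degenerate=False,
        empirical_mean=e_mean, empirical_variance=e_var,
        analytic_mean=a_mean, analytic_variance=a_var,
        gamma_fit=params, ks_statistic=ks.statistic, ks_pvalue=ks.pvalue,
    )
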