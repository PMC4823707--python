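"""Synthetic count matrices with the two observed noise regimes.

The default generator is a Poisson-gamma hierarchy: each replicate count is
Poisson(Lambda) with Lambda ~ Gamma(shape k, scale mu/k), giving

    E[count] = mu,   Var[count] = mu + mu^2 / k.

At small mu the Poisson term dominates (variance ~ mean, the low-read
regime); at large mu the quadratic term dominates (variance ~ mean^2/k, the
high-read gamma regime).  One mechanism therefore reproduces both regimes
of real technical-replicate data.  Two purist modes exist for calibration
work: ``pure_gamma_rounded`` (rounded gamma draws, no Poisson stage) and
``pure_poisson``.

Defaults mirror a sextuplicate technical-replicate design: 6 replicates
per group, gamma shape k = 10 (a replicate-level coefficient of variation
of about 32% in the high-read regime).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .pcr import simulate_sequencing_library

__all__ = ["SyntheticConfig", "generate_matrix", "generate_from_pcr"]

NOISE_MODELS = ("poisson_gamma", "pure_gamma_rounded", "pure_poisson")


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic count generator.

    mean_grid:
        Either an explicit array of per-gene baseline means (length
        n_genes) or a (low, high) tuple from which means are drawn
        log-uniformly.
    gamma_shape:
        k > 0; the high-read squared coefficient of variation is 1/k.
    de_fraction:
        Fraction of genes whose group-1 mean is multiplied by a fold
        change (only meaningful with n_groups = 2).
    fold_changes:
        A single fold change or a sequence sampled uniformly per DE gene.
    """

    n_genes: int
    n_reps_per_group: int = 6
    n_groups: int = 2
    mean_grid: tuple[float, float] | Sequence[float] = (0.5, 10_000.0)
    gamma_shape: float = 10.0
    noise_model: str = "poisson_gamma"
    de_fraction: float = 0.0
    fold_changes: float | Sequence[float] = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_reps_per_group < 1:
            raise ValueError("n_reps_per_group must be >= 1")
        if self.n_groups not in (1, 2):
            raise ValueError("n_groups must be 1 or 2")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")


def _baseline_means(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.mean_grid, tuple) and len(cfg.mean_grid) == 2 and np.isscalar(cfg.mean_grid[0]):
        low, high = float(cfg.mean_grid[0]), float(cfg.mean_grid[1])
        if not (0 < low <= high):
            raise ValueError("mean_grid bounds must satisfy 0 < low <= high")
        if low == high:
            return np.full(cfg.n_genes, low)
        return np.exp(rng.uniform(np.log(low), np.log(high), size=cfg.n_genes))
    means = np.asarray(cfg.mean_grid, dtype=float)
    if means.shape != (cfg.n_genes,):
        raise ValueError("explicit mean_grid must have length n_genes")
    if (means <= 0).any():
        raise ValueError("baseline means must be positive")
    return means.copy()


def _draw_counts(
    means: np.ndarray, n_reps: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Genes x replicates count draws for one group given per-gene means."""
    shape = (means.size, n_reps)
    mu = means[:, None]
    if cfg.noise_model == "pure_poisson":
        return rng.poisson(np.broadcast_to(mu, shape)).astype(float)
    lam = rng.gamma(cfg.gamma_shape, mu / cfg.gamma_shape, size=shape)
    if cfg.noise_model == "pure_gamma_rounded":
        # round half to even so the counts stay valid for integer-only tests
        return np.rint(lam)
    return rng.poisson(lam).astype(float)


def generate_matrix(cfg: SyntheticConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a count matrix plus its ground-truth table.

    Returns the matrix (groups named "A" and "B") and a truth table with
    per-gene configured group means, DE status, and true fold change.
    """
    rng = np.random.default_rng(cfg.seed)
    means0 = _baseline_means(cfg, rng)
    gene_ids = [f"gene{str(i + 1).zfill(len(str(cfg.n_genes)))}" for i in range(cfg.n_genes)]

    n_de = int(round(cfg.de_fraction * cfg.n_genes)) if cfg.n_groups == 2 else 0
    is_de = np.zeros(cfg.n_genes, dtype=bool)
    fold = np.ones(cfg.n_genes)
    if n_de > 0:
        de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
        is_de[de_idx] = True
        if np.isscalar(cfg.fold_changes):
            fold[de_idx] = float(cfg.fold_changes)
        else:
            fold[de_idx] = rng.choice(np.asarray(cfg.fold_changes, dtype=float), size=n_de)
    means1 = means0 * fold

    blocks, sample_ids, labels = [], [], {}
    group_names = ["A", "B"][: cfg.n_groups]
    group_means = [means0, means1]
    for g, name in enumerate(group_names):
        blocks.append(_draw_counts(group_means[g], cfg.n_reps_per_group, cfg, rng))
        for r in range(cfg.n_reps_per_group):
            sid = f"{name}_rep{r + 1}"
            sample_ids.append(sid)
            labels[sid] = name
    data = pd.DataFrame(np.hstack(blocks), index=gene_ids, columns=sample_ids)

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mean_A": means0,
            "mean_B": means1 if cfg.n_groups == 2 else means0,
            "is_de": is_de,
            "true_fold_change": fold,
        }
    )
    return CountMatrix(data, labels), truth


def generate_from_pcr(
    abundances,
    cycles: int,
    efficiency: float,
    depth: int | None = None,
    n_reps: int = 6,
    seed: int = 0,
) -> CountMatrix:
    """Mechanism-level generator: each replicate is an independent
    amplify-then-sample sequencing library over the same template pool.

    Unlike :func:`generate_matrix`, the noise here is produced by the
    branching-process amplification itself, not drawn from a distributional
    assumption — it links the PCR mechanism to the observed quadratic
    mean-variance phenomenology.
    """
    abundances = np.asarray(abundances, dtype=np.int64)
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(n_reps)]
    cols = [
        simulate_sequencing_library(abundances, cycles, efficiency, depth=depth, seed=cs)
        for cs in child_seeds
    ]
    gene_ids = [f"gene{str(i + 1).zfill(len(str(abundances.size)))}" for i in range(abundances.size)]
    sample_ids = [f"rep{r + 1}" for r in range(n_reps)]
    data = pd.DataFrame(
        np.column_stack(cols).astype(float), index=gene_ids, columns=sample_ids
    )
    return CountMatrix(data, {s: "all" for s in sample_ids})
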