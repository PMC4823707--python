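"""Monte-Carlo evaluation of the differential-expression tests.

Quantifies, on synthetic data with known truth, (i) per-method type-I error
on null genes and power on DE genes, (ii) between-method agreement as rank
correlation of -log10 p, and (iii) genes where one method calls a strong
effect while another sees none — the hallmark of the Poisson test's
anticonservatism under gamma noise.

Rates are estimated per-gene across many genes in a few large matrices
rather than one gene across many matrices; under gene independence the two
are equivalent and the former is far faster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .de import DeResult, run_de_table
from .synthetic import SyntheticConfig, generate_matrix

__all__ = [
    "EvalReport",
    "type1_power_simulation",
    "method_agreement",
    "discordance_report",
]


@dataclass(frozen=True)
class EvalReport:
    """Rejection rates and agreement summary of one evaluation run."""

    methods: tuple[str, ...]
    alpha: float
    n_sims: int
    n_null_genes: int
    n_de_genes: int
    rejection_rate_null: dict[str, float]
    power_by_fold_change: dict[str, dict[float, float]]
    agreement: dict[tuple[str, str], float]


def type1_power_simulation(
    cfg: SyntheticConfig,
    methods=("poisson_glm", "gamma_glm", "crt_ttest"),
    alpha: float = 0.05,
    n_sims: int = 1,
    seed: int = 0,
    pseudocount: float = 0.0,
) -> EvalReport:
    """Estimate null rejection rates and power for each method.

    Generates ``n_sims`` independent matrices from ``cfg`` (seeds derived
    from ``seed``), runs every method on every gene, and tallies rejections
    at level ``alpha`` separately over null genes (type-I error) and over
    DE genes grouped by true fold change (power).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    methods = tuple(methods)
    tables: dict[str, list[DeResult]] = {meth: [] for meth in methods}
    null_flags: list[bool] = []
    fold: list[float] = []
    for s in range(n_sims):
        sim_cfg = replace(cfg, seed=(seed + 100_003 * s) % (2**31))
        matrix, truth = generate_matrix(sim_cfg)
        results = run_de_table(matrix, methods=methods, pseudocount=pseudocount)
        for r in results:
            tables[r.method].append(r)
        null_flags.extend((~truth["is_de"]).tolist())
        fold.extend(truth["true_fold_change"].tolist())
    null_flags_arr = np.asarray(null_flags, dtype=bool)
    fold_arr = np.asarray(fold, dtype=float)

    rejection_null: dict[str, float] = {}
    power: dict[str, dict[float, float]] = {}
    for meth in methods:
        p = np.array(
            [r.p_value if r.p_value is not None else np.nan for r in tables[meth]]
        )
        reject = p < alpha
        nulls = null_flags_arr & np.isfinite(p)
        rejection_null[meth] = float(reject[nulls].mean()) if nulls.any() else float("nan")
        power[meth] = {}
        for fc in sorted(set(fold_arr[~null_flags_arr])):
            sel = (~null_flags_arr) & (fold_arr == fc) & np.isfinite(p)
            power[meth][float(fc)] = float(reject[sel].mean()) if sel.any() else float("nan")

    agreement = method_agreement(tables) if len(methods) >= 2 else {}
    return EvalReport(
        methods=methods,
        alpha=alpha,
        n_sims=n_sims,
        n_null_genes=int(null_flags_arr.sum()),
        n_de_genes=int((~null_flags_arr).sum()),
        rejection_rate_null=rejection_null,
        power_by_fold_change=power,
        agreement=agreement,
    )


def _p_map(table: list[DeResult]) -> dict[str, float]:
    return {r.gene_id: r.p_value for r in table if r.p_value is not None}


def method_agreement(
    de_tables: dict[str, list[DeResult]], correlation: str = "spearman"
) -> dict[tuple[str, str], float]:
    """Pairwise correlation of -log10 p between methods on shared genes.

    Spearman by default: p-value clouds are heavy-tailed, so rank
    correlation is the stable summary (Pearson available as an option).
    Genes with an undefined p-value in either method are dropped pairwise.
    """
    if correlation not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation {correlation!r}")
    methods = list(de_tables)
    maps = {meth: _p_map(t) for meth, t in de_tables.items()}
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            shared = [g for g in maps[a] if g in maps[b]]
            if len(shared) < 3:
                raise ValueError(
                    f"methods {a!r} and {b!r} share only {len(shared)} genes with "
                    "defined p-values; need >= 3"
                )
            # -log10 p; tiny floor avoids infinities from p == 0
            xa = -np.log10(np.maximum([maps[a][g] for g in shared], 1e-300))
            xb = -np.log10(np.maximum([maps[b][g] for g in shared], 1e-300))
            if correlation == "spearman":
                rho = stats.spearmanr(xa, xb).statistic
            else:
                rho = stats.pearsonr(xa, xb).statistic
            out[(a, b)] = float(rho)
    return out


@dataclass(frozen=True)
class DiscordantGene:
    """A gene that one method calls strongly while another does not."""

    gene_id: str
    method_strict: str
    p_strict_value: float
    method_lenient: str
    p_lenient_value: float
    mean_g0: float
    mean_g1: float


def discordance_report(
    de_tables: dict[str, list[DeResult]],
    p_strict: float = 1e-4,
    p_lenient: float = 0.5,
) -> list[DiscordantGene]:
    """Genes with method-A p < ``p_strict`` and method-B p > ``p_lenient``.

    Screens every ordered pair of methods.  The default thresholds (1e-4
    and 0.5) flag the extreme disagreements where an anticonservative test
    reports overwhelming significance on genes another test considers null.
    """
    if not (0.0 < p_strict < p_lenient < 1.0):
        raise ValueError("need 0 < p_strict < p_lenient < 1")
    maps = {meth: _p_map(t) for meth, t in de_tables.items()}
    means = {
        meth: {r.gene_id: (r.mean_g0, r.mean_g1) for r in t}
        for meth, t in de_tables.items()
    }
    out: list[DiscordantGene] = []
    for a in de_tables:
        for b in de_tables:
            if a == b:
                continue
            for gene in maps[a]:
                if gene not in maps[b]:
                    continue
                pa, pb = maps[a][gene], maps[b][gene]
                if pa < p_strict and pb > p_lenient:
                    m0, m1 = means[a][gene]
                    out.append(
                        DiscordantGene(gene, a, pa, b, pb, m0, m1)
                    )
    return out
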