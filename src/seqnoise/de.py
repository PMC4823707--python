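"""Two-group differential-expression tests on count data.

Three tests of equal group means, all on the raw count scale:

* ``glm_identity_poisson_test`` — identity-link Poisson GLM Wald test.
  The two-group identity-link model is saturated, so the fitted group means
  are the sample means and the Wald statistic has the closed form
  z = (m1 - m0) / sqrt(m0/n0 + m1/n1), referenced to the standard normal
  (dispersion fixed at 1).
* ``glm_identity_gamma_test`` — identity-link gamma GLM Wald test with
  Pearson-estimated dispersion phi, t = (m1 - m0) /
  sqrt(phi * (m0^2/n0 + m1^2/n1)), referenced to Student t with N-2 df.
* ``crt_ttest`` — cube-root transformation followed by a two-sample t-test.
  The cube root approximately normalizes gamma-distributed data
  (Wilson–Hilferty), so ordinary normal-theory methods apply.

Under gamma (quadratic mean-variance) noise, the Poisson test severely
underestimates the variance of high-read genes and is anticonservative;
the gamma GLM and the cube-root t-test agree closely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DeResult",
    "glm_identity_poisson_test",
    "glm_identity_gamma_test",
    "crt_ttest",
    "bh_adjust",
    "run_de_table",
    "DE_METHODS",
]


@dataclass(frozen=True)
class DeResult:
    """One gene's two-group test result for one method."""

    gene_id: str
    mean_g0: float
    mean_g1: float
    log2_ratio: float | None
    method: str
    statistic: float | None
    df: float | None
    dispersion: float | None
    p_value: float | None
    p_adjusted: float | None = None


def _as_group(y, name: str) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 2:
        raise ValueError(f"group {name} needs >= 2 values")
    if not np.all(np.isfinite(y)):
        raise ValueError(f"group {name} contains non-finite values")
    return y


def _log2_ratio(m0: float, m1: float) -> float | None:
    if m0 > 0 and m1 > 0:
        return float(np.log2(m1 / m0))
    return None


def glm_identity_poisson_test(y0, y1, gene_id: str = "") -> DeResult:
    """Identity-link Poisson GLM Wald test for a difference in group means.

    Requires integer counts.  The variance of each observation is taken to
    be its mean (dispersion 1), so the test is exact only when the counts
    really are Poisson; under gamma noise it is strongly anticonservative.
    """
    y0 = _as_group(y0, "y0")
    y1 = _as_group(y1, "y1")
    for name, y in (("y0", y0), ("y1", y1)):
        if (y < 0).any() or not np.all(y == np.round(y)):
            raise ValueError(f"Poisson GLM requires non-negative integer counts ({name})")
    m0, m1 = float(y0.mean()), float(y1.mean())
    if m0 == 0 and m1 == 0:
        warnings.warn("both group means zero: Poisson test undefined", stacklevel=2)
        return DeResult(gene_id, m0, m1, None, "poisson_glm", None, None, None, None)
    se = np.sqrt(m0 / y0.size + m1 / y1.size)
    z = (m1 - m0) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return DeResult(
        gene_id, m0, m1, _log2_ratio(m0, m1), "poisson_glm",
        float(z), None, None, float(p),
    )


def glm_identity_gamma_test(y0, y1, gene_id: str = "") -> DeResult:
    """Identity-link gamma GLM Wald test with Pearson dispersion.

    The gamma variance function is V(mu) = mu^2, so the Pearson dispersion
    is phi = sum((y - mu_g)^2 / mu_g^2) / (N - 2) and the Wald statistic is
    referenced to Student t with N - 2 degrees of freedom.  Strictly
    positive data are required; apply a pseudocount upstream for zeros.
    """
    y0 = _as_group(y0, "y0")
    y1 = _as_group(y1, "y1")
    if (y0 <= 0).any() or (y1 <= 0).any():
        raise ValueError(
            "gamma GLM requires strictly positive values; "
            "add a pseudocount (e.g. pseudocount=0.5) to handle zeros"
        )
    m0, m1 = float(y0.mean()), float(y1.mean())
    n0, n1 = y0.size, y1.size
    df = n0 + n1 - 2
    phi = (((y0 - m0) ** 2 / m0**2).sum() + ((y1 - m1) ** 2 / m1**2).sum()) / df
    if phi == 0:
        warnings.warn("zero Pearson dispersion: gamma test undefined", stacklevel=2)
        return DeResult(
            gene_id, m0, m1, _log2_ratio(m0, m1), "gamma_glm",
            None, float(df), 0.0, None,
        )
    se = np.sqrt(phi * (m0**2 / n0 + m1**2 / n1))
    t = (m1 - m0) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return DeResult(
        gene_id, m0, m1, _log2_ratio(m0, m1), "gamma_glm",
        float(t), float(df), float(phi), float(p),
    )


def crt_ttest(y0, y1, variant: str = "welch", gene_id: str = "") -> DeResult:
    """Cube-root transformation followed by a two-sample t-test.

    ``variant`` selects Welch (default, unequal variances) or the pooled
    equal-variance t-test.  Effect size (``log2_ratio``) is reported on the
    original count scale.
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    y0 = _as_group(y0, "y0")
    y1 = _as_group(y1, "y1")
    if (y0 < 0).any() or (y1 < 0).any():
        raise ValueError("cube-root transform expects non-negative values")
    x0, x1 = np.cbrt(y0), np.cbrt(y1)
    m0, m1 = float(y0.mean()), float(y1.mean())
    if x0.var(ddof=1) == 0 and x1.var(ddof=1) == 0:
        warnings.warn("zero variance in both transformed groups", stacklevel=2)
        return DeResult(
            gene_id, m0, m1, _log2_ratio(m0, m1), "crt_ttest",
            None, None, None, None,
        )
    res = stats.ttest_ind(x1, x0, equal_var=(variant == "pooled"))
    return DeResult(
        gene_id, m0, m1, _log2_ratio(m0, m1), "crt_ttest",
        float(res.statistic), float(res.df), None, float(res.pvalue),
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


DE_METHODS = {
    "poisson_glm": glm_identity_poisson_test,
    "gamma_glm": glm_identity_gamma_test,
    "crt_ttest": crt_ttest,
}


def run_de_table(
    m: CountMatrix,
    methods=("poisson_glm", "gamma_glm", "crt_ttest"),
    pseudocount: float = 0.0,
    adjust: str = "none",
) -> list[DeResult]:
    """Run the requested tests on every gene of a two-group matrix.

    The pseudocount (when non-zero) is added to the gamma-GLM inputs only;
    the other methods see the raw values.  ``adjust="bh"`` appends
    Benjamini–Hochberg adjusted p-values per method across genes.
    """
    groups = m.groups
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    if adjust not in ("none", "bh"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    unknown = [meth for meth in methods if meth not in DE_METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    g0, g1 = groups
    v0 = m.group_values(g0).to_numpy(dtype=float)
    v1 = m.group_values(g1).to_numpy(dtype=float)
    results: list[DeResult] = []
    for method in methods:
        func = DE_METHODS[method]
        per_method: list[DeResult] = []
        for i, gene in enumerate(m.gene_ids):
            y0, y1 = v0[i], v1[i]
            if method == "gamma_glm" and pseudocount:
                y0, y1 = y0 + pseudocount, y1 + pseudocount
            per_method.append(func(y0, y1, gene_id=gene))
        if adjust == "bh":
            defined = [r for r in per_method if r.p_value is not None]
            if defined:
                adj = bh_adjust([r.p_value for r in defined])
                adj_map = {id(r): a for r, a in zip(defined, adj)}
                per_method = [
                    replace(r, p_adjusted=float(adj_map[id(r)]))
                    if id(r) in adj_map else r
                    for r in per_method
                ]
        results.extend(per_method)
    return results
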