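"""Per-gene mean-variance diagnostics and Poisson/gamma goodness of fit.

Across technical replicates, sequencing counts show two noise regimes:
low-read genes have variance approximately equal to the mean (Poisson-like),
while high-read genes have variance scaling with the square of the mean,
the signature of a gamma distribution with constant shape (variance =
mean^2 / shape).  This module quantifies the regime of each gene — sample
moments, a log-log mean-variance line fit, and per-gene one-sample
Kolmogorov–Smirnov tests against plug-in Poisson and gamma models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .counts import CountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMoments",
    "MeanVarianceFit",
    "GammaParams",
    "GofResult",
    "KsResult",
    "gene_moments",
    "fit_mean_variance_line",
    "classify_regime",
    "fit_gamma_moments",
    "ks_gof_poisson",
    "ks_gof_gamma",
    "gof_scan",
]


@dataclass(frozen=True)
class GeneMoments:
    """Sample mean and unbiased variance of one gene across replicates."""

    gene_id: str
    group: str
    n_reps: int
    mean: float
    variance: float


@dataclass(frozen=True)
class MeanVarianceFit:
    """OLS fit of log10(variance+1) on log10(mean+1) over selected genes."""

    slope: float
    intercept: float
    n_genes_used: int
    mean_threshold_used: float

    def formula(self) -> str:
        sign = "+" if self.intercept >= 0 else "-"
        return (
            f"log10(var+1) = {self.slope:.3f} log10(mean+1) "
            f"{sign} {abs(self.intercept):.3f}"
        )


@dataclass(frozen=True)
class GammaParams:
    """Gamma(shape k, scale theta): mean = k*theta, variance = k*theta^2."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float


@dataclass(frozen=True)
class GofResult:
    """Per-gene per-group KS goodness of fit under plug-in Poisson and gamma.

    ``p_poisson`` is None for non-integer inputs; ``p_gamma`` is None for
    degenerate (zero-variance or zero-mean) genes.
    """

    gene_id: str
    group: str
    mean: float
    p_poisson: float | None
    p_gamma: float | None
    lambda_hat: float
    gamma_shape: float | None
    gamma_scale: float | None


def gene_moments(m: CountMatrix, group: str) -> list[GeneMoments]:
    """Mean and unbiased (n-1) variance per gene across one group's replicates."""
    sub = m.group_values(group)
    n = sub.shape[1]
    if n < 2:
        raise ValueError(f"group {group!r} has {n} sample(s); need >= 2 for moments")
    means = sub.mean(axis=1)
    variances = sub.var(axis=1, ddof=1)
    return [
        GeneMoments(str(g), group, n, float(means[g]), float(variances[g]))
        for g in sub.index
    ]


def fit_mean_variance_line(
    moments: list[GeneMoments], mean_threshold: float = 10.0
) -> MeanVarianceFit:
    """OLS line through (log10(mean+1), log10(variance+1)) for genes with
    mean strictly above ``mean_threshold``.

    A slope near 1 indicates Poisson-like noise (variance = mean); a slope
    near 2 indicates the quadratic, gamma-like law (variance ∝ mean^2).
    """
    sel = [mo for mo in moments if mo.mean > mean_threshold]
    if len(sel) < 3:
        raise ValueError(
            f"need >= 3 genes with mean > {mean_threshold}; got {len(sel)}"
        )
    x = np.log10(np.array([mo.mean for mo in sel]) + 1.0)
    y = np.log10(np.array([mo.variance for mo in sel]) + 1.0)
    slope, intercept = np.polyfit(x, y, 1)
    return MeanVarianceFit(float(slope), float(intercept), len(sel), mean_threshold)


def classify_regime(moments: GeneMoments, mean_threshold: float = 10.0) -> str:
    """``"high_read"`` iff the gene's mean strictly exceeds the threshold."""
    return "high_read" if moments.mean > mean_threshold else "low_read"


def fit_gamma_moments(replicates: np.ndarray) -> GammaParams:
    """Method-of-moments gamma fit: shape = mean^2/var, scale = var/mean.

    Closed-form and stable at the very small replicate numbers (n = 6)
    typical of technical-replicate designs.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 replicates for a gamma fit")
    if (x < 0).any():
        raise ValueError("gamma fit requires non-negative values")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    if mean == 0:
        raise ValueError("gamma fit undefined for zero mean")
    if var == 0:
        raise ValueError("degenerate gamma fit: zero sample variance")
    return GammaParams(shape=mean**2 / var, scale=var / mean)


def fit_gamma_mle(replicates: np.ndarray) -> GammaParams:
    """Maximum-likelihood gamma fit (location fixed at 0); opt-in alternative."""
    x = np.asarray(replicates, dtype=float)
    if (x <= 0).any():
        raise ValueError("gamma MLE requires strictly positive values")
    shape, _, scale = stats.gamma.fit(x, floc=0)
    return GammaParams(shape=float(shape), scale=float(scale))


def _ks_pvalue_asymptotic(d: float, n: int) -> float:
    """Asymptotic (Kolmogorov) p-value for a one-sample KS statistic."""
    return float(stats.kstwobign.sf(d * np.sqrt(n)))


def ks_gof_poisson(replicates: np.ndarray) -> KsResult:
    """One-sample KS test of integer counts against Poisson(lambda = mean).

    The model CDF is a step function, so the sup distance is evaluated at
    every support point, taking both one-sided gaps across the jump there:
    F_model(k) - F_emp(k-1) and F_emp(k) - F_model(k-1).  The p-value comes
    from the asymptotic Kolmogorov distribution with the plug-in mean, a
    combination documented as conservative.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 replicates for the KS test")
    if not np.all(np.isfinite(x)) or not np.all(x == np.round(x)) or (x < 0).any():
        raise ValueError("Poisson KS requires non-negative integer counts")
    n = x.size
    lam = float(x.mean())
    kmax = int(x.max())
    ks = np.arange(kmax + 1)
    f_model = stats.poisson.cdf(ks, lam)
    f_emp = np.searchsorted(np.sort(x), ks, side="right") / n
    f_model_prev = np.concatenate([[0.0], f_model[:-1]])
    f_emp_prev = np.concatenate([[0.0], f_emp[:-1]])
    d = float(np.max(np.maximum(f_model - f_emp_prev, f_emp - f_model_prev)))
    d = max(d, 0.0)
    return KsResult(statistic=d, pvalue=_ks_pvalue_asymptotic(d, n))


def ks_gof_gamma(replicates: np.ndarray) -> KsResult:
    """One-sample KS test against the method-of-moments gamma fit.

    Zero values sit at the gamma CDF's origin (model CDF 0).  Degenerate
    inputs (zero variance or zero mean) yield an NA result with a warning
    rather than an error, so whole-matrix scans never abort.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 replicates for the KS test")
    try:
        params = fit_gamma_moments(x)
    except ValueError as exc:
        warnings.warn(f"gamma KS undefined: {exc}", stacklevel=2)
        return KsResult(statistic=float("nan"), pvalue=float("nan"))
    res = stats.kstest(x, stats.gamma(params.shape, loc=0, scale=params.scale).cdf)
    return KsResult(statistic=float(res.statistic), pvalue=float(res.pvalue))


def _is_integral(x: np.ndarray) -> bool:
    return bool(np.all(x == np.round(x)))


def gof_scan(m: CountMatrix) -> list[GofResult]:
    """Both KS goodness-of-fit p-values for every gene in every group.

    Non-integer replicate vectors get ``p_poisson = None``; zero-variance
    vectors get ``p_gamma = None`` (degenerate gamma fit).
    """
    out: list[GofResult] = []
    for group in m.groups:
        sub = m.group_values(group)
        if sub.shape[1] < 3:
            raise ValueError(f"group {group!r} needs >= 3 replicates for KS")
        for gene in sub.index:
            x = sub.loc[gene].to_numpy(dtype=float)
            lam = float(x.mean())
            if _is_integral(x):
                p_pois = ks_gof_poisson(x).pvalue
            else:
                warnings.warn(
                    f"gene {gene!r}: non-integer values, Poisson KS skipped",
                    stacklevel=2,
                )
                p_pois = None
            shape = scale = None
            p_gamma = None
            if lam > 0 and float(x.var(ddof=1)) > 0:
                params = fit_gamma_moments(x)
                shape, scale = params.shape, params.scale
                p_gamma = ks_gof_gamma(x).pvalue
            out.append(
                GofResult(
                    gene_id=str(gene),
                    group=group,
                    mean=lam,
                    p_poisson=p_pois,
                    p_gamma=p_gamma,
                    lambda_hat=lam,
                    gamma_shape=shape,
                    gamma_scale=scale,
                )
            )
    return out
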