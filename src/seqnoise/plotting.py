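"""Diagnostic plots: mean-variance scatter, GOF p-values, volcano, agreement."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .de import DeResult
from .diagnostics import GeneMoments, GofResult, MeanVarianceFit

__all__ = [
    "plot_mean_variance",
    "plot_gof_pvalues",
    "plot_volcano",
    "plot_method_agreement",
]


def plot_mean_variance(
    moments: list[GeneMoments],
    fit: MeanVarianceFit | None,
    path: str | Path,
) -> None:
    """Scatter of log10(variance+1) vs log10(mean+1) with the diagonal
    (variance = mean) and, if given, the fitted high-read line."""
    x = np.log10(np.array([m.mean for m in moments]) + 1.0)
    y = np.log10(np.array([m.variance for m in moments]) + 1.0)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=6, alpha=0.4, color="black")
    lim = max(1.0, x.max() if x.size else 1.0, y.max() if y.size else 1.0)
    grid = np.linspace(0, lim, 50)
    ax.plot(grid, grid, color="blue", lw=1, label="variance = mean")
    if fit is not None:
        ax.plot(
            grid, fit.slope * grid + fit.intercept,
            color="red", ls="--", lw=1, label=fit.formula(),
        )
    ax.set_xlabel("log10(mean + 1)")
    ax.set_ylabel("log10(variance + 1)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_gof_pvalues(results: list[GofResult], path: str | Path) -> None:
    """KS p-values under Poisson (blue) and gamma (red) vs log10 mean."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for attr, color, label in (
        ("p_poisson", "blue", "Poisson"),
        ("p_gamma", "red", "gamma"),
    ):
        pts = [(r.mean, getattr(r, attr)) for r in results if getattr(r, attr) is not None]
        if pts:
            mean, p = zip(*pts)
            ax.scatter(np.log10(np.asarray(mean) + 1.0), p, s=6, alpha=0.5,
                       color=color, label=label)
    ax.set_xlabel("log10(mean + 1)")
    ax.set_ylabel("KS goodness-of-fit p-value")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_volcano(results: list[DeResult], path: str | Path) -> None:
    """log2 mean ratio vs -log10 p, one color per method."""
    fig, ax = plt.subplots(figsize=(6, 4))
    methods = sorted({r.method for r in results})
    cmap = plt.get_cmap("tab10")
    for i, meth in enumerate(methods):
        pts = [
            (r.log2_ratio, r.p_value)
            for r in results
            if r.method == meth and r.log2_ratio is not None and r.p_value is not None
        ]
        if pts:
            lr, p = map(np.asarray, zip(*pts))
            ax.scatter(lr, -np.log10(np.maximum(p, 1e-300)), s=6, alpha=0.5,
                       color=cmap(i), label=meth)
    ax.set_xlabel("log2 ratio (group1 / group0)")
    ax.set_ylabel("-log10 p")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_method_agreement(
    p_a: np.ndarray, p_b: np.ndarray, label_a: str, label_b: str, path: str | Path
) -> None:
    """-log10 p of one method against another, with the identity line."""
    xa = -np.log10(np.maximum(p_a, 1e-300))
    xb = -np.log10(np.maximum(p_b, 1e-300))
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xa, xb, s=6, alpha=0.5, color="black")
    lim = max(1.0, xa.max(), xb.max())
    ax.plot([0, lim], [0, lim], color="grey", lw=1)
    ax.set_xlabel(f"-log10 p ({label_a})")
    ax.set_ylabel(f"-log10 p ({label_b})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
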