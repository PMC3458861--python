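"""Vector-graphic summaries of an HFC analysis."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["metric_scatter", "effect_forest", "burden_vs_diversity"]


def metric_scatter(div: pd.DataFrame, path) -> None:
    """Pairwise scatter of the three diversity indices."""
    pairs = [("sMLH", "IR"), ("IR", "HL"), ("HL", "sMLH")]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, (a, b) in zip(axes, pairs):
        ax.scatter(div[a], div[b], s=8, alpha=0.5, color="k")
        ax.set_xlabel(a)
        ax.set_ylabel(b)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def effect_forest(effects: pd.DataFrame, path, title="single-locus effect sizes") -> None:
    """Forest plot of per-locus partial-correlation effect sizes with CIs."""
    eff = effects.dropna(subset=["r"])
    y = np.arange(len(eff))[::-1]
    fig, ax = plt.subplots(figsize=(5, 0.35 * len(eff) + 1.5))
    ax.errorbar(
        eff["r"],
        y,
        xerr=[eff["r"] - eff["ci_lo"], eff["ci_hi"] - eff["r"]],
        fmt="o",
        color="k",
        capsize=2,
    )
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(eff.index)
    ax.set_xlabel("effect size (partial r)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def burden_vs_diversity(
    data: pd.DataFrame, response: str, path, metric: str = "IR"
) -> None:
    """Scatter of burden against the diversity metric with a quadratic fit."""
    x = data[metric].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(x, y, s=10, alpha=0.4, color="k")
    coefs = np.polyfit(x, y, 2)
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, np.polyval(coefs, grid), color="firebrick")
    ax.set_xlabel(f"{metric} (standardized)")
    ax.set_ylabel(response)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
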