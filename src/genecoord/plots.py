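"""Optional matplotlib views: paired spectrum bars and a volcano plot."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .coordination import SpectrumComparison  # noqa: E402

__all__ = ["plot_spectrum_comparison", "plot_volcano"]


def plot_spectrum_comparison(comparison: SpectrumComparison, path: str | Path) -> None:
    """Side-by-side bars of the two groups' normalized eigenvalues by rank."""
    n = len(comparison.spectrum_a.values)
    x = np.arange(1, n + 1)
    width = 0.38
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(x - width / 2, comparison.spectrum_a.values, width, label=comparison.group_a)
    ax.bar(x + width / 2, comparison.spectrum_b.values, width, label=comparison.group_b)
    ax.set_xlabel("eigenvalue rank")
    ax.set_ylabel("normalized eigenvalue")
    ax.set_xticks(x)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_volcano(table: pd.DataFrame, path: str | Path, use_adjusted: bool = True) -> None:
    """logFC vs -log10 p, colored by up/down/ns status."""
    p = table["p_adj" if use_adjusted else "p_raw"].clip(lower=1e-300)
    colors = {"up": "tab:blue", "down": "tab:green", "ns": "lightgray"}
    fig, ax = plt.subplots(figsize=(4.5, 3.6))
    for status, color in colors.items():
        sub = table[table["status"] == status]
        ax.scatter(sub["logFC"], -np.log10(p.loc[sub.index]), s=12, c=color, label=status)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.legend(markerscale=1.5, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
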