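"""Optional plot export: metagene line plots and translocation heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .translocapture import TranslocationMatrix


def plot_metagene(metagenes: dict, path: str | Path, ylabel: str = "rate (%)") -> None:
    """Line plot of metagene mean rates; one line per group label."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, df in metagenes.items():
        ax.plot(df.index, df["mean"], label=label)
    ax.axvline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("distance from cut (bp)")
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_translocation_heatmap(matrix: TranslocationMatrix, path: str | Path) -> None:
    """Heatmap of per-pair translocation rates (diagonal masked: cis)."""
    rates = matrix.rates_frame().copy()
    for lid in rates.index:
        rates.loc[lid, lid] = float("nan")
    fig, ax = plt.subplots(figsize=(7, 6))
    im = ax.imshow(rates.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(rates.columns)), rates.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(rates.index)), rates.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="translocation rate")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
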