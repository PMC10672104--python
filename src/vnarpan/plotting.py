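"""Heat-map rendering of abundance and fold-change matrices.

Abundance runs red (low) to green (high) on a log scale; fold change runs
white to blue beside it.  Not-detected cells are hatched grey.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns


def _draw(ax, df: pd.DataFrame, cmap: str, label: str, log: bool) -> None:
    data = df.copy()
    if log:
        with np.errstate(divide="ignore"):
            data = np.log10(data)
    sns.heatmap(
        data,
        ax=ax,
        cmap=cmap,
        mask=df.isna(),
        yticklabels=False if len(df) > 60 else True,
        cbar_kws={"label": label},
    )
    ax.set_facecolor("0.85")
    ax.set_title(label)


def abundance_heatmap(values: pd.DataFrame, path) -> None:
    """Single-panel CDR3 abundance heat map (red->green, log10 %)."""
    fig, ax = plt.subplots(figsize=(4, max(3, min(12, len(values) / 40))))
    _draw(ax, values, "RdYlGn", "log10 abundance (%)", log=True)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def combined_heatmap(
    abundance: pd.DataFrame, fold_change: pd.DataFrame, path
) -> None:
    """Abundance (red->green) beside fold change (white->blue), shared rows."""
    fold_change = fold_change.reindex(abundance.index)
    fig, (ax1, ax2) = plt.subplots(
        1,
        2,
        figsize=(7, max(3, min(12, len(abundance) / 40))),
        gridspec_kw={"width_ratios": [abundance.shape[1], max(1, fold_change.shape[1])]},
    )
    _draw(ax1, abundance, "RdYlGn", "log10 abundance (%)", log=True)
    _draw(ax2, fold_change, "Blues", "fold change vs reference", log=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
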