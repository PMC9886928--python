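"""Cosmetic plotting helpers for trajectories and sweep heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genetics import ALLELE_NAMES
from .scenarios import ReplicateResult


def plot_trajectories(results: list[ReplicateResult], ax=None):
    """Allele-frequency trajectories among queens, one faint line per replicate."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {"WT": "tab:blue", "GD": "tab:red", "RE": "tab:green", "NF": "tab:orange"}
    for result in results:
        for k, name in enumerate(ALLELE_NAMES):
            ax.plot(result.generation, result.allele_freqs[:, k],
                    color=colors[name], alpha=0.3, lw=1)
    for name, color in colors.items():
        ax.plot([], [], color=color, label=name)
    ax.set_xlabel("generation")
    ax.set_ylabel("allele frequency among queens")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    return ax


def plot_sweep_heatmap(table: pd.DataFrame, x: str, y: str,
                       value: str = "suppression_rate", ax=None):
    """Heatmap of a two-axis drive-parameter sweep table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = table.pivot(index=y, columns=x, values=value)
    im = ax.imshow(grid.to_numpy(), origin="lower", aspect="auto",
                   vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(np.arange(grid.shape[1]), [f"{v:g}" for v in grid.columns])
    ax.set_yticks(np.arange(grid.shape[0]), [f"{v:g}" for v in grid.index])
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    ax.figure.colorbar(im, ax=ax, label=value)
    return ax
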