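"""Small summary plots: choice-rate bars and recovery heatmaps."""

from __future__ import annotations

import numpy as np


def plot_choice_rates(summary_df, ax=None, **bar_kwargs):
    """Bar chart of per-stimulus test choice rates with SEM error bars.

    ``summary_df`` is the frame produced by
    :func:`ierl.simulate.test_choice_rates`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.arange(len(summary_df))
    ax.bar(x, summary_df["choice_rate"], yerr=summary_df["sem"],
           capsize=3, **bar_kwargs)
    ax.set_xticks(x, summary_df["option_id"])
    ax.set_ylabel("test choice rate")
    ax.set_ylim(0, 1)
    return ax


def plot_confusion(confusion, which="frequencies", ax=None):
    """Heatmap of a model-recovery confusion matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = getattr(confusion, which)
    im = ax.imshow(grid.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(grid.columns)), grid.columns, rotation=45)
    ax.set_yticks(range(len(grid.index)), grid.index)
    ax.set_xlabel("fitted model")
    ax.set_ylabel("generating model")
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            ax.text(j, i, f"{grid.iat[i, j]:.2f}", ha="center", va="center",
                    color="white")
    ax.figure.colorbar(im, ax=ax, label=which)
    return ax
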