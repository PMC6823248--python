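"""A single plotting helper: module-score heat map."""

from __future__ import annotations

import pandas as pd


def score_heatmap(scores: pd.DataFrame, ax=None, cmap: str = "RdBu_r"):
    """Heat map of a module x sample score table (e.g. ``ModuleScores.es``).

    Returns the matplotlib Axes; centered at zero so suppressed modules
    read blue and enriched modules red.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(1 + 0.5 * scores.shape[1], 1 + 0.4 * scores.shape[0])
        )
    vmax = float(scores.abs().to_numpy().max()) or 1.0
    im = ax.imshow(scores.to_numpy(), cmap=cmap, vmin=-vmax, vmax=vmax,
                   aspect="auto")
    ax.set_xticks(range(scores.shape[1]), scores.columns, rotation=90)
    ax.set_yticks(range(scores.shape[0]), scores.index)
    ax.figure.colorbar(im, ax=ax, label="enrichment score")
    return ax
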