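"""Debug heatmap with domain calls overlaid (requires matplotlib)."""

from __future__ import annotations

import numpy as np

from .assembly import TADForest
from .matrix import ContactMap

# level-keyed colors, outermost first
LEVEL_PALETTE = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e"]


def plot_calls(cmap: ContactMap, forest: TADForest, ax=None, log: bool = True):
    """Upper-triangle heatmap of the matrix with called domains as squares."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    vals = cmap.values
    if log:
        vals = np.log1p(np.clip(vals, 0, None))
    ax.imshow(vals, cmap="Reds", interpolation="nearest")
    for t in forest.tads:
        color = LEVEL_PALETTE[min(t.level, len(LEVEL_PALETTE)) - 1]
        a, b = t.left - 0.5, t.right - 0.5
        ax.plot([a, b, b, a, a], [a, a, b, b, a], color=color, lw=1.2)
    ax.set_xlabel("bin")
    ax.set_ylabel("bin")
    return ax
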