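"""Diagnostic scatter of the fitted curve with score colouring."""

from __future__ import annotations

import numpy as np

from .curves import evaluate_curve


def plot_fit(model, x, y, scores=None, path=None, colour_by: str = "aggregation"):
    """Scatter the cohort, overlay the fitted curve, colour by a score.

    Returns the matplotlib figure; writes to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    c = None
    if scores is not None and colour_by in getattr(scores, "columns", []):
        c = scores[colour_by]
    sc = ax.scatter(x, y, c=c, s=12, cmap="viridis", alpha=0.8)
    lo, hi = model.params_.domain
    grid = np.linspace(lo, hi, 400)
    ax.plot(grid, evaluate_curve(model.params_, grid), "k-", lw=1.5)
    ax.set_xlabel("Amyloid-PET burden (Centiloid)")
    ax.set_ylabel("CSF-Aβ42")
    if c is not None:
        fig.colorbar(sc, ax=ax, label=f"{colour_by} score")
    ax.set_title(
        f"form={model.params_.form}, pseudo-R²={model.pseudo_r2_:.3f}"
    )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
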