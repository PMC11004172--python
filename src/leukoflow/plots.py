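"""Dot-plot rendering for manual-vs-AI gating comparison.

Draws the canonical ALOT 2-D marker views (the same channel pairs used for
density images), coloring events by cell-type label, so an AI gating result
can be compared side by side with manual gates.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .features import transform_events
from .fcs_io import EventMatrix
from .patient_model import DEFAULT_PAIRS
from .vocab import CELL_TYPES

_CMAP = plt.get_cmap("tab20")
LABEL_COLORS = {c: _CMAP(i % 20) for i, c in enumerate(CELL_TYPES)}


def dot_plots(
    em: EventMatrix,
    labels: np.ndarray,
    out_png: str | Path,
    pairs=DEFAULT_PAIRS,
    max_points: int = 20_000,
    seed: int = 0,
    title: str | None = None,
) -> Path:
    """Write a grid of label-colored dot plots for one sample."""
    t = transform_events(em)
    labels = np.asarray(labels)
    if len(labels) > max_points:
        idx = np.random.default_rng(seed).choice(
            len(labels), size=max_points, replace=False
        )
        t, labels = t[idx], labels[idx]
    ncol = 3
    nrow = int(np.ceil(len(pairs) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.2 * nrow))
    for ax, (cx, cy) in zip(np.ravel(axes), pairs):
        xi, yi = em.panel.index(cx), em.panel.index(cy)
        for c in CELL_TYPES:
            mask = labels == c
            if mask.any():
                ax.scatter(
                    t[mask, xi], t[mask, yi], s=1, color=LABEL_COLORS[c], label=c
                )
        ax.set_xlabel(cx)
        ax.set_ylabel(cy)
    for ax in np.ravel(axes)[len(pairs):]:
        ax.axis("off")
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=LABEL_COLORS[c], label=c)
        for c in CELL_TYPES
        if (labels == c).any()
    ]
    fig.legend(handles=handles, loc="lower right", fontsize=6, ncol=2)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    out_png = Path(out_png)
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return out_png
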