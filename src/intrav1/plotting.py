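"""Figure writers: visual-field graph plots and gaze heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .retinotopy import RetinotopicMap  # noqa: E402


def visual_field_graph(
    rmap: RetinotopicMap,
    edge_i: np.ndarray,
    edge_j: np.ndarray,
    edge_values: np.ndarray,
    path: Path,
    title: str = "",
) -> None:
    """Edges drawn between vertex visual-field positions, colored by weight."""
    fig, ax = plt.subplots(figsize=(5, 5))
    vmax = np.abs(edge_values).max() if len(edge_values) else 1.0
    cmap = plt.get_cmap("coolwarm")
    for a, b, v in zip(edge_i, edge_j, edge_values):
        ax.plot(
            [rmap.vf_x[a], rmap.vf_x[b]],
            [rmap.vf_y[a], rmap.vf_y[b]],
            color=cmap(0.5 + 0.5 * v / vmax),
            lw=0.8,
            alpha=0.8,
        )
    ax.scatter(rmap.vf_x, rmap.vf_y, s=6, c="k", zorder=3)
    ax.add_patch(plt.Circle((0, 0), 0.3, color="0.7", zorder=4))
    ax.axhline(0, color="0.85", lw=0.5)
    ax.axvline(0, color="0.85", lw=0.5)
    ax.set_xlabel("visual field x (DVA)")
    ax.set_ylabel("visual field y (DVA)")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def heatmap_figure(
    grids: dict[str, np.ndarray], path: Path, title: str = ""
) -> None:
    """Panel of fixation-duration heatmaps (one per label)."""
    n = len(grids)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3), squeeze=False)
    for ax, (label, grid) in zip(axes[0], grids.items()):
        im = ax.imshow(grid, cmap="viridis", origin="upper")
        ax.set_title(label, fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
        fig.colorbar(im, ax=ax, fraction=0.046)
    if title:
        fig.suptitle(title)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
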