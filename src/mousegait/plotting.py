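"""Static plots: ROC curves, distance-versus-time traces, group means,
and annotated-frame overlays for debugging detection."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import PAW_LABELS, ClassifiedFootfall
from .evaluate import ROCPoint, auc, optimal_threshold
from .frames import FrameImage

__all__ = [
    "plot_roc",
    "plot_paw_distance",
    "plot_group_means",
    "annotate_frame",
]

_PAW_COLORS = {
    "Left-Front": "tab:blue",
    "Right-Front": "tab:orange",
    "Left-Rear": "tab:green",
    "Right-Rear": "tab:red",
    "Unclassified": "tab:gray",
}


def plot_roc(points: Sequence[ROCPoint], path: str | Path, title: str = "ROC") -> Path:
    """Empirical ROC polyline with the optimal threshold marked."""
    pts = sorted((p.fpr, p.tpr) for p in points if np.isfinite(p.fpr) and np.isfinite(p.tpr))
    xs = [0.0] + [p[0] for p in pts] + [1.0]
    ys = [0.0] + [p[1] for p in pts] + [1.0]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(xs, ys, marker="o", label=f"AUC = {auc(points):.3f}")
    ax.plot([0, 1], [0, 1], ls="--", c="gray", lw=1)
    ot, opt = optimal_threshold(points)
    ax.scatter([opt.fpr], [opt.tpr], c="red", zorder=5, label=f"OT = {ot:g}")
    ax.set_xlabel("False-positive rate")
    ax.set_ylabel("True-positive rate")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_paw_distance(positions: pd.DataFrame, path: str | Path, fps: float = 60.0) -> Path:
    """Distance travelled (x centroid) against time for each paw: contact
    phases show as horizontal segments, swings as the jumps between them."""
    fig, ax = plt.subplots(figsize=(7, 4))
    for paw, grp in positions.groupby("paw"):
        ax.plot(
            grp["frame_index"] / fps,
            grp["x"],
            marker=".",
            ls="none",
            ms=3,
            color=_PAW_COLORS.get(paw),
            label=paw,
        )
    ax.set_xlabel("Time (s)")
    ax.set_ylabel("Distance along trackway (px)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_group_means(
    values: pd.DataFrame,
    path: str | Path,
    group_col: str = "group",
    value_col: str = "value",
    title: Optional[str] = None,
) -> Path:
    """Plain group mean +- 95% CI bar plot (no hypothesis testing)."""
    fig, ax = plt.subplots(figsize=(5, 4))
    stats = values.groupby(group_col)[value_col].agg(["mean", "sem", "count"])
    ci = 1.96 * stats["sem"]
    ax.bar(stats.index, stats["mean"], yerr=ci, capsize=4, color="tab:blue", alpha=0.8)
    ax.set_ylabel(value_col)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def annotate_frame(
    frame: FrameImage, footfalls: Sequence[ClassifiedFootfall], path: str | Path
) -> Path:
    """Save the frame with bounding boxes and labels of its footfalls."""
    fig, ax = plt.subplots(figsize=(8, 8 * frame.height / frame.width))
    ax.imshow(frame.pixels)
    for f in footfalls:
        if f.frame_index != frame.frame_index:
            continue
        x_min, y_min, x_max, y_max = f.cluster.bounding_box
        color = _PAW_COLORS.get(f.label.value, "white")
        ax.add_patch(
            plt.Rectangle(
                (x_min - 0.5, y_min - 0.5),
                x_max - x_min + 1,
                y_max - y_min + 1,
                fill=False,
                edgecolor=color,
                lw=1.5,
            )
        )
        ax.text(x_min, y_min - 2, f.label.value, color=color, fontsize=7)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
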