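"""Report figures: violins, regression curves, PCA biplot, orientation disk.

Each function returns a matplotlib Figure; callers save as SVG (or any
backend format).  Figures are deliberately plain — publication styling is
the caller's job.
"""

from __future__ import annotations

from typing import Any

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import stereographic_projection

__all__ = ["violin_by_group", "regression_plot", "pca_biplot", "orientation_disk"]


def violin_by_group(table: pd.DataFrame, metric: str, groups: list[str] | None = None):
    """Violin of one metric per age group, split by element."""
    groups = groups or list(dict.fromkeys(table["age_group"]))
    elements = list(dict.fromkeys(table["element"]))
    fig, axes = plt.subplots(1, len(elements), figsize=(4 * len(elements), 3),
                             squeeze=False)
    for ax, element in zip(axes[0], elements):
        sub = table[table.element == element]
        data = [sub.loc[sub.age_group == g, metric].to_numpy() for g in groups]
        ax.violinplot(data, showmeans=True)
        ax.set_xticks(range(1, len(groups) + 1), groups, rotation=45)
        ax.set_title(f"{element} {metric}")
    fig.tight_layout()
    return fig


def regression_plot(x: np.ndarray, y: np.ndarray, poly_coefficients: np.ndarray,
                    xlabel: str = "logBM", ylabel: str = "metric"):
    """Scatter with the fitted polynomial curve."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(x, y, s=12, alpha=0.7)
    grid = np.linspace(np.min(x), np.max(x), 200)
    ax.plot(grid, np.polyval(poly_coefficients, grid), color="k")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return fig


def pca_biplot(pca_result: dict[str, Any], color_by: pd.Series | None = None):
    """Scores on PC1/PC2 with loading vectors."""
    scores = pca_result["scores"]
    loadings = pca_result["loadings"]
    ratio = pca_result["explained_ratio"]
    fig, ax = plt.subplots(figsize=(4.5, 4))
    if color_by is not None:
        for label in dict.fromkeys(color_by):
            sel = (color_by == label).to_numpy()
            ax.scatter(scores.iloc[sel, 0], scores.iloc[sel, 1], s=14, label=str(label))
        ax.legend(fontsize=7)
    else:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=14)
    scale = 0.8 * np.abs(scores.iloc[:, :2].to_numpy()).max()
    for name, row in loadings.iterrows():
        ax.annotate(name, (row.iloc[0] * scale, row.iloc[1] * scale), fontsize=7)
        ax.arrow(0, 0, row.iloc[0] * scale, row.iloc[1] * scale,
                 alpha=0.4, width=0.002, color="gray")
    ax.set_xlabel(f"PC1 ({100 * ratio.iloc[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * ratio.iloc[1]:.0f}%)")
    fig.tight_layout()
    return fig


def orientation_disk(azimuth: np.ndarray, plunge: np.ndarray,
                     size: np.ndarray | None = None,
                     group: pd.Series | None = None):
    """Lambert equal-area lower-hemisphere disk of fabric orientations;
    optional marker size channel (e.g. anisotropy)."""
    px, py = stereographic_projection(np.asarray(azimuth), np.asarray(plunge))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.add_patch(plt.Circle((0, 0), 1.0, fill=False, color="k", lw=0.8))
    s = 20 if size is None else 10 + 80 * np.asarray(size) / max(np.max(size), 1e-9)
    if group is not None:
        for label in dict.fromkeys(group):
            sel = (group == label).to_numpy()
            ax.scatter(px[sel], py[sel], s=np.atleast_1d(s)[sel] if np.ndim(s) else s,
                       label=str(label), alpha=0.8)
        ax.legend(fontsize=7, loc="upper right")
    else:
        ax.scatter(px, py, s=s, alpha=0.8)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    return fig
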