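"""Presentation plots: DMR heatmap, PCA scatter, ROC curve.

These are convenience views over the numeric outputs; nothing downstream
depends on them. Requires matplotlib (the ``plot`` extra).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_region_heatmap(centered_table: pd.DataFrame, path: str | Path,
                        groups: pd.Series | None = None) -> None:
    """Regions x samples heatmap of mean-centered percent methylation."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * centered_table.shape[1]), 6))
    vmax = np.nanmax(np.abs(centered_table.to_numpy())) or 1.0
    im = ax.imshow(centered_table.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(centered_table.shape[1]))
    ax.set_xticklabels(centered_table.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel(f"{centered_table.shape[0]} regions")
    fig.colorbar(im, ax=ax, label="% methylation relative to region mean")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_pca_scores(scores: pd.DataFrame, variance_explained: np.ndarray,
                    path: str | Path, groups: pd.Series | None = None) -> None:
    """PC1/PC2 scatter of sample scores, colored by group when given."""
    plt = _mpl()
    fig, ax = plt.subplots(figsize=(5, 5))
    if groups is not None:
        for g in pd.unique(groups.loc[scores.index]):
            mask = (groups.loc[scores.index] == g).to_numpy()
            ax.scatter(scores.iloc[mask, 0], scores.iloc[mask, 1], label=str(g), s=30)
        ax.legend()
    else:
        ax.scatter(scores.iloc[:, 0], scores.iloc[:, 1], s=30)
    ax.set_xlabel(f"PC1 ({100 * variance_explained[0]:.0f}%)")
    ax.set_ylabel(f"PC2 ({100 * variance_explained[1]:.0f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_roc(y_true: np.ndarray, scores: np.ndarray, positive_class: str,
             path: str | Path) -> None:
    """ROC curve of classifier margins on a labelled test cohort."""
    from sklearn.metrics import roc_auc_score, roc_curve

    plt = _mpl()
    y = (np.asarray(y_true) == positive_class).astype(int)
    fpr, tpr, _ = roc_curve(y, scores)
    auc = roc_auc_score(y, scores)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(fpr, tpr, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey")
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"ROC AUC = {auc:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
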