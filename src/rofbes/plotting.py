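"""Basic diagnostic plots: fitness-vs-epoch curves and fold-wise ROC curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless rendering

import matplotlib.pyplot as plt
import numpy as np

from .metrics import roc_auc

__all__ = ["plot_fitness_history", "plot_roc_curves"]


def plot_fitness_history(histories, labels=None, ax=None):
    """Best-fitness-per-epoch curves for one or more optimization runs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    if np.ndim(histories[0]) == 0:
        histories = [histories]
    for i, hist in enumerate(histories):
        label = labels[i] if labels else f"run {i + 1}"
        ax.plot(range(1, len(hist) + 1), hist, label=label)
    ax.set_xlabel("epoch")
    ax.set_ylabel("best fitness (F1)")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize="small")
    return ax


def plot_roc_curves(fold_scores, ax=None):
    """Combined ROC curves across folds.

    ``fold_scores`` is a list of (y_true, positive-class scores) pairs.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for i, (y_true, scores) in enumerate(fold_scores, start=1):
        curve, auc = roc_auc(y_true, scores)
        if auc is None:
            continue
        ax.plot(curve[:, 0], curve[:, 1], label=f"fold {i} (AUC={auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", linewidth=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize="x-small")
    return ax
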