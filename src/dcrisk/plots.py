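"""Plotting helpers for embedding, clustering and classifier results.

All functions draw onto a provided matplotlib Axes (or create one) and
return it, so they compose with user figure layouts; callers save with
``ax.figure.savefig(...)``.
"""

from __future__ import annotations

import numpy as np


def _get_ax(ax=None):
    if ax is None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def scatter_embedding(result, ax=None):
    """Two-component scatter coloured by group code (1-5)."""
    ax = _get_ax(ax)
    sc = ax.scatter(result.coordinates[:, 0], result.coordinates[:, 1],
                    c=result.labels, cmap="viridis", s=12)
    ax.set_xlabel(f"{result.method.upper()}1")
    ax.set_ylabel(f"{result.method.upper()}2")
    ax.figure.colorbar(sc, ax=ax, label="group code")
    return ax


def plot_roc(report, ax=None):
    """ROC curve with the AUC in the legend."""
    ax = _get_ax(ax)
    label = "ROC" if report.auc is None else f"AUC = {report.auc:.3f}"
    ax.plot(report.fpr, report.tpr, label=label)
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax


def plot_loss_history(loss_history, ax=None, step: int = 10):
    """Per-epoch boxplots of batch losses (every ``step``-th epoch)."""
    ax = _get_ax(ax)
    epochs = list(range(0, len(loss_history), step))
    ax.boxplot([loss_history[e] for e in epochs],
               positions=np.arange(len(epochs)), widths=0.6,
               flierprops={"markersize": 2})
    ax.set_xticks(np.arange(len(epochs)), [str(e + 1) for e in epochs])
    ax.set_xlabel("epoch")
    ax.set_ylabel("batch loss")
    return ax


def plot_dendrogram(clustering, ax=None):
    """Dendrogram of a hierarchical-clustering result."""
    from scipy.cluster import hierarchy

    ax = _get_ax(ax)
    hierarchy.dendrogram(clustering.linkage, labels=clustering.sample_ids,
                         ax=ax, no_labels=len(clustering.sample_ids) > 40)
    ax.set_ylabel("Euclidean distance")
    return ax
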