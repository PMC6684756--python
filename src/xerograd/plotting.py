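"""Matplotlib views of evaluation outputs (side effects only; every
acceptance-relevant number lives in the CSV/JSON bundle)."""

from __future__ import annotations

import numpy as np

from .evaluate import mann_whitney_auc
from .model import PDGrid


def plot_partial_dependence(pd_grid: PDGrid, ax=None):
    """1D line or 2D filled-contour PD plot with percentile rug marks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if len(pd_grid.features) == 1:
        (f,) = pd_grid.features
        ax.plot(pd_grid.grid[0], pd_grid.pd_values, color="C0")
        ax.set_xlabel(f)
        ax.set_ylabel("partial dependence (P(G2 xerostomia))")
        ymin = float(np.min(pd_grid.pd_values))
        ax.plot(
            pd_grid.rug_percentiles[f],
            np.full_like(pd_grid.rug_percentiles[f], ymin),
            "|", color="k", markersize=8,
        )
    else:
        f0, f1 = pd_grid.features
        cf = ax.contourf(pd_grid.grid[0], pd_grid.grid[1], pd_grid.pd_values.T, levels=20)
        ax.figure.colorbar(cf, ax=ax, label="P(G2 xerostomia)")
        ax.set_xlabel(f0)
        ax.set_ylabel(f1)
        ax.plot(pd_grid.rug_percentiles[f0],
                np.full_like(pd_grid.rug_percentiles[f0], ax.get_ylim()[0]),
                "|", color="k")
        ax.plot(np.full_like(pd_grid.rug_percentiles[f1], ax.get_xlim()[0]),
                pd_grid.rug_percentiles[f1], "_", color="k")
    return ax


def plot_roc(scores, labels, ax=None):
    """Empirical ROC curve with the Mann-Whitney AUC in the legend."""
    import matplotlib.pyplot as plt

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    tp = np.concatenate([[0], np.cumsum(labels[order] == 1)])
    fp = np.concatenate([[0], np.cumsum(labels[order] == 0)])
    tpr = tp / max(tp[-1], 1)
    fpr = fp / max(fp[-1], 1)
    if ax is None:
        _, ax = plt.subplots()
    auc = mann_whitney_auc(scores, labels)
    ax.plot(fpr, tpr, label=f"AUC = {auc:.2f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend()
    return ax
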