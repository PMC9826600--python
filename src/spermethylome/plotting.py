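"""Minimal heatmap / dendrogram exports for clustering results."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.cluster.hierarchy import dendrogram, leaves_list, linkage


def beta_heatmap(
    data: pd.DataFrame,
    labels: pd.Series | None = None,
    path: str | Path | None = None,
    method: str = "average",
    metric: str = "euclidean",
):
    """Probes x samples heatmap with sample dendrogram on top."""
    X = data.to_numpy(float)
    X = X[~np.isnan(X).any(axis=1)]
    Z = linkage(X.T, method=method, metric=metric)
    order = leaves_list(Z)
    fig, (ax_d, ax_h) = plt.subplots(
        2, 1, figsize=(max(6, 0.4 * data.shape[1]), 8),
        gridspec_kw={"height_ratios": [1, 4]},
    )
    dendrogram(Z, ax=ax_d, labels=list(data.columns), leaf_rotation=90)
    ax_d.set_yticks([])
    im = ax_h.imshow(X[:, order], aspect="auto", cmap="RdYlBu_r", vmin=0, vmax=1)
    ax_h.set_xticks(range(len(order)))
    names = [data.columns[i] for i in order]
    if labels is not None:
        names = [f"{n} ({labels.get(n, '?')})" for n in names]
    ax_h.set_xticklabels(names, rotation=90, fontsize=7)
    ax_h.set_yticks([])
    ax_h.set_ylabel(f"{X.shape[0]} probes")
    fig.colorbar(im, ax=ax_h, label="beta")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
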