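"""Plotting: the cluster-PCA score plot with 95% confidence ellipses.

Plotting is a reporting convenience, not part of the statistical
contract; the ellipse is the chi-square(2 df) radius of the per-cluster
2-D score covariance under a multivariate-normal assumption.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy.stats import chi2


def confidence_ellipse(points: np.ndarray, level: float = 0.95,
                       n_vertices: int = 100) -> np.ndarray:
    """Vertices of the ``level`` confidence ellipse of 2-D points."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need >= 3 two-dimensional points")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    radius = np.sqrt(chi2.ppf(level, df=2))
    vals, vecs = np.linalg.eigh(cov)
    vals = np.clip(vals, 0.0, None)
    theta = np.linspace(0, 2 * np.pi, n_vertices)
    circle = np.column_stack([np.cos(theta), np.sin(theta)])
    return center + radius * circle * np.sqrt(vals) @ vecs.T


def plot_cluster_pca(pca_result, assignments: pd.Series, labels: pd.Series,
                     path, level: float = 0.95) -> None:
    """Score plot of PC1/PC2 coloured by cluster, labelled by group,
    with per-cluster confidence ellipses."""
    scores = pca_result.scores.iloc[:, :2]
    assignments = pd.Series(assignments).reindex(scores.index)
    labels = pd.Series(labels).reindex(scores.index)
    fig, ax = plt.subplots(figsize=(7, 6))
    cmap = plt.get_cmap("tab10")
    for i, c in enumerate(sorted(assignments.unique())):
        mask = assignments == c
        pts = scores[mask].values
        ax.scatter(pts[:, 0], pts[:, 1], s=18, color=cmap(i % 10),
                   label=f"cluster {c}")
        if pts.shape[0] >= 3:
            ellipse = confidence_ellipse(pts, level=level)
            ax.plot(ellipse[:, 0], ellipse[:, 1], color=cmap(i % 10), lw=1)
    for (x, y), g in zip(scores.values, labels.values):
        ax.annotate(str(g), (x, y), fontsize=5, alpha=0.6)
    ev = pca_result.explained_frac
    ax.set_xlabel(f"PC1 ({100 * ev[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * ev[1]:.1f}%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
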