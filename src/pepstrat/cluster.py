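"""Unsupervised structure: binary-distance hierarchical k-means,
principal component analysis and cluster composition metrics.

Hierarchical k-means (hkmeans) cuts a Ward.D2 tree built on the binary
(asymmetric Jaccard) distance into k groups and refines the cut with
standard Euclidean k-means started from the group centroids.  The
hierarchical stage carries the binary-distance semantics; the k-means
loop runs on the raw 0/1 rows, where centroids are well defined.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .features import BinaryMatrix

logger = logging.getLogger("pepstrat")


def round_half_up(x) -> np.ndarray | float:
    """Round halves away from zero toward +inf (85.29 -> 85,
    76.92 -> 77, 90.5 -> 91), the convention of reported integer
    percentages."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


# ---------------------------------------------------------------------------
# Binary distance
# ---------------------------------------------------------------------------

def binary_distance(x, y) -> float:
    """Asymmetric Jaccard dissimilarity between two 0/1 vectors:
    discordant positions over positions where at least one is 1; two
    all-zero vectors are at distance 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("binary distance requires 0/1 entries")
    active = (x == 1) | (y == 1)
    if not active.any():
        return 0.0
    discordant = (x != y) & active
    return float(discordant.sum() / active.sum())


def binary_distance_matrix(values: np.ndarray) -> np.ndarray:
    """Condensed pairwise binary-distance matrix over the rows."""
    return pdist(np.asarray(values, dtype=bool), metric="jaccard")


# ---------------------------------------------------------------------------
# Composition metrics
# ---------------------------------------------------------------------------

@dataclass
class CompositionMetrics:
    """Cluster-vs-group accounting.

    ``composition``: clusters x groups count table.  ``homogeneity``:
    per-cluster dominant-group share in integer % (NaN for an empty
    cluster).  ``coverage``: per (cluster, group) % of the group's
    rows captured, integer %.
    """

    composition: pd.DataFrame
    homogeneity: pd.Series
    coverage: pd.DataFrame
    dominant_group: pd.Series
    homogeneity_raw: pd.Series | None = None  # unrounded percentages
    coverage_raw: pd.DataFrame | None = None


def composition_metrics(assignments, labels) -> CompositionMetrics:
    """Count each cluster's group membership and report homogeneity
    (dominant-group share of the cluster) and coverage (share of each
    group captured by the cluster), as integer percentages rounded
    half-up."""
    assignments = pd.Series(np.asarray(assignments))
    labels = pd.Series(np.asarray(labels))
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels must have equal length")
    composition = pd.crosstab(assignments, labels)
    composition.index.name = "cluster"
    composition.columns.name = "group"
    sizes = composition.sum(axis=1)
    dominant = composition.idxmax(axis=1)
    homogeneity_raw = pd.Series(
        [100.0 * composition.loc[c, dominant[c]] / sizes[c]
         if sizes[c] > 0 else np.nan for c in composition.index],
        index=composition.index, name="homogeneity_pct")
    homogeneity = homogeneity_raw.map(
        lambda v: np.nan if pd.isna(v) else round_half_up(v))
    group_totals = composition.sum(axis=0)
    coverage_raw = composition.div(group_totals, axis=1) * 100.0
    coverage = coverage_raw.apply(round_half_up)
    return CompositionMetrics(composition=composition, homogeneity=homogeneity,
                              coverage=coverage, dominant_group=dominant,
                              homogeneity_raw=homogeneity_raw,
                              coverage_raw=coverage_raw)


# ---------------------------------------------------------------------------
# Hierarchical k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: pd.Series       # row id -> cluster id in 1..k
    centers: np.ndarray          # k x n_bins (fractional after k-means)
    metrics: CompositionMetrics | None
    hierarchical_assignments: pd.Series
    inertia: float


def _within_ss(values: np.ndarray, assignments: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(assignments):
        block = values[assignments == c]
        total += ((block - block.mean(axis=0)) ** 2).sum()
    return float(total)


def hkmeans(b: BinaryMatrix, k: int, labels: pd.Series | None = None,
            max_iter: int = 300) -> ClusterResult:
    """Hierarchical k-means on a binary matrix.

    Steps: pairwise binary distances; Ward.D2 agglomeration
    (Lance-Williams update on the supplied dissimilarities); cut into
    k groups; initial centers = within-group means of the binary rows;
    Euclidean k-means from those centers to convergence.  When true
    group labels are given, composition/homogeneity/coverage are
    computed against them.
    """
    values = b.values.values.astype(float)
    n = values.shape[0]
    if k > n:
        raise ValueError(f"k ({k}) exceeds the number of rows ({n})")
    if values.shape[1] < 1:
        raise ValueError("need at least one bin")
    if k == n:
        hier = np.arange(1, n + 1)
    else:
        dist = binary_distance_matrix(values)
        tree = linkage(dist, method="ward")
        hier = fcluster(tree, t=k, criterion="maxclust")
    present = np.unique(hier)
    centers0 = np.vstack([values[hier == c].mean(axis=0) for c in present])
    while centers0.shape[0] < k:  # degenerate cut: re-seed at farthest row
        gaps = ((values[:, None, :] - centers0[None]) ** 2).sum(-1).min(1)
        centers0 = np.vstack([centers0, values[int(np.argmax(gaps))]])
        logger.warning("hierarchical cut yielded fewer than k groups; "
                       "re-seeded a center at the farthest row")
    if k == 1 or n == k:
        final = hier
        centers = centers0
        inertia = _within_ss(values, final)
    else:
        km = KMeans(n_clusters=k, init=centers0, n_init=1, max_iter=max_iter)
        km.fit(values)
        final = km.labels_ + 1
        centers = km.cluster_centers_
        inertia = float(km.inertia_)
        if len(np.unique(final)) < k:
            logger.warning("k-means left an empty cluster; sklearn re-seeded it")
    assignments = pd.Series(final, index=b.values.index, name="cluster")
    hier_s = pd.Series(hier, index=b.values.index, name="cluster_hier")
    metrics = None
    if labels is not None:
        labels = pd.Series(labels).reindex(b.values.index)
        metrics = composition_metrics(assignments.values, labels.values)
    return ClusterResult(assignments=assignments, centers=centers,
                         metrics=metrics, hierarchical_assignments=hier_s,
                         inertia=inertia)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame        # rows x components
    loadings: pd.DataFrame      # bins x components, orthonormal columns
    explained_frac: np.ndarray  # per-component fraction of total variance


def pca(values: pd.DataFrame) -> PcaResult:
    """PCA of a (binary or intensity) matrix: columns mean-centered, no
    scaling; components from the SVD of the centered matrix, explained
    fraction = eigenvalue share of the covariance trace."""
    frame = values.values if hasattr(values, "values") else np.asarray(values)
    index = values.index if hasattr(values, "index") else pd.RangeIndex(len(frame))
    columns = values.columns if hasattr(values, "columns") else None
    frame = np.asarray(frame, dtype=float)
    if frame.shape[0] < 2 or frame.shape[1] < 1:
        raise ValueError("PCA needs at least 2 rows and 1 column")
    centered = frame - frame.mean(axis=0)
    if not np.any(centered):
        raise ValueError("PCA undefined for zero total variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    n_comp = min(frame.shape[0] - 1, frame.shape[1])
    u, s, vt = u[:, :n_comp], s[:n_comp], vt[:n_comp]
    eigvals = s ** 2
    explained = eigvals / eigvals.sum()
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    scores = pd.DataFrame(u * s, index=index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=columns, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, explained_frac=explained)
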