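"""Coarse region division and per-region outlier elimination.

Cells are partitioned into ``g`` regions with mini-batch k-means; within
each region the squared Mahalanobis distance to the region centroid is
tested against a chi-squared quantile and flagged cells are dropped from
the region mean, yielding cleaned centroids.  Under a Gaussian region model
D^2 ~ chi2(N) with N the embedding dimension, so at significance alpha a
fraction ~alpha of genuinely Gaussian cells is flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import chi2
from sklearn.cluster import MiniBatchKMeans

from .io_preprocess import EmbeddingMatrix

logger = logging.getLogger(__name__)

#: Ridge added to near-singular region covariances, as a fraction of the
#: average eigenvalue trace(S)/N.
COV_RIDGE = 1e-6


@dataclass
class OutlierTest:
    """Per-cell squared Mahalanobis distances and the chi2 cutoff used."""

    distances_sq: np.ndarray
    dof: int
    alpha: float
    threshold: float


@dataclass
class RegionPartition:
    """Region assignment, centroids and outlier flags for all cells.

    Regions are indexed 0..g-1 in memory; file output prints them 1-based.
    """

    region_of: np.ndarray          # (P,) int, 0..g-1
    centroids: np.ndarray          # (g, N) raw centroids
    outlier_flag: np.ndarray       # (P,) bool
    clean_centroids: np.ndarray    # (g, N) means over non-outlier members
    region_sizes: np.ndarray       # (g,) non-outlier counts

    @property
    def g(self) -> int:
        return self.centroids.shape[0]

    def members(self, r: int, clean: bool = False) -> np.ndarray:
        idx = np.flatnonzero(self.region_of == r)
        if clean:
            idx = idx[~self.outlier_flag[idx]]
        return idx


# ---------------------------------------------------------------------------
# region division
# ---------------------------------------------------------------------------

def divide_regions(M: EmbeddingMatrix, g: int, seed: int) -> RegionPartition:
    """Partition cells into exactly ``g`` nonempty regions.

    Mini-batch k-means (k-means++ init, batch size min(1024, P), 100
    iterations) is fit on the rows in a canonical lexicographic order so the
    result is invariant to the order cells appear on disk; empty regions are
    repaired by splitting off the farthest cell of the largest region.
    Centroids are recomputed as exact means of the final assignment.
    """
    X = M.values
    P = X.shape[0]
    if g > P:
        raise ValueError(f"g={g} exceeds the number of cells P={P}")
    if g < 2:
        raise ValueError("g must be >= 2")

    order = np.lexsort(X.T[::-1])  # canonical row order -> permutation equivariance
    km = MiniBatchKMeans(
        n_clusters=g,
        init="k-means++",
        batch_size=min(1024, P),
        max_iter=100,
        n_init=3,
        random_state=seed % (2**31),
    )
    labels_sorted = km.fit_predict(X[order])
    labels = np.empty(P, dtype=int)
    labels[order] = labels_sorted

    # repair empty regions: peel the farthest cell off the largest region
    sizes = np.bincount(labels, minlength=g)
    while (sizes == 0).any():
        empty = int(np.argmin(sizes))
        largest = int(np.argmax(sizes))
        idx = np.flatnonzero(labels == largest)
        centroid = X[idx].mean(axis=0)
        far = idx[int(np.argmax(((X[idx] - centroid) ** 2).sum(axis=1)))]
        labels[far] = empty
        sizes = np.bincount(labels, minlength=g)
        logger.info("repaired empty region %d from region %d", empty, largest)

    centroids = np.zeros((g, X.shape[1]))
    for r in range(g):
        centroids[r] = X[labels == r].mean(axis=0)
    return RegionPartition(
        region_of=labels,
        centroids=centroids,
        outlier_flag=np.zeros(P, dtype=bool),
        clean_centroids=centroids.copy(),
        region_sizes=sizes.copy(),
    )


# ---------------------------------------------------------------------------
# Mahalanobis / chi-squared outlier test
# ---------------------------------------------------------------------------

def mahalanobis_sq(x: np.ndarray, c: np.ndarray, cov: np.ndarray) -> float:
    """Squared Mahalanobis distance (x-c)' Sigma^-1 (x-c)."""
    d = np.asarray(x, dtype=float) - np.asarray(c, dtype=float)
    try:
        sol = linalg.solve(cov, d, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance matrix: {exc}") from exc
    return float(d @ sol)


def _regularized_cov(cells: np.ndarray) -> np.ndarray:
    cov = np.cov(cells, rowvar=False)
    n_feat = cells.shape[1]
    ridge = COV_RIDGE * np.trace(cov) / n_feat
    return cov + max(ridge, 1e-12) * np.eye(n_feat)


def flag_outliers(
    cells: np.ndarray, centroid: np.ndarray, alpha: float
) -> tuple[OutlierTest, np.ndarray]:
    """Flag cells whose squared Mahalanobis distance to the centroid reaches
    the (1-alpha) chi2(N) quantile.

    The covariance is the region's own sample covariance with a small ridge;
    the caller must ensure n > N + 2 so it is identifiable.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    cells = np.asarray(cells, dtype=float)
    n, n_feat = cells.shape
    cov = _regularized_cov(cells)
    diffs = cells - np.asarray(centroid, dtype=float)
    try:
        chol = linalg.cho_factor(cov)
    except linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance after regularization: {exc}") from exc
    d2 = np.einsum("ij,ij->i", diffs, linalg.cho_solve(chol, diffs.T).T)
    d2 = np.maximum(d2, 0.0)
    threshold = float(chi2.ppf(1.0 - alpha, df=n_feat))
    test = OutlierTest(distances_sq=d2, dof=n_feat, alpha=alpha, threshold=threshold)
    return test, d2 >= threshold


def update_centroids(
    M: EmbeddingMatrix, partition: RegionPartition, alpha: float
) -> RegionPartition:
    """Run the outlier test in every region and recompute cleaned centroids.

    Regions with n <= N + 2 cells skip the test (covariance unidentifiable).
    If a test would flag every cell of a region, the cell with the smallest
    distance is kept so no region is left empty.
    """
    X = M.values
    n_feat = X.shape[1]
    flags = np.zeros(X.shape[0], dtype=bool)
    clean = partition.centroids.copy()
    g = partition.g
    for r in range(g):
        idx = np.flatnonzero(partition.region_of == r)
        if idx.size <= n_feat + 2:
            continue
        try:
            test, region_flags = flag_outliers(X[idx], partition.centroids[r], alpha)
        except ValueError as exc:
            raise ValueError(f"region {r}: {exc}") from exc
        if region_flags.all():
            keep = int(np.argmin(test.distances_sq))
            region_flags[keep] = False
            logger.info("region %d: all cells flagged, keeping the most central", r)
        flags[idx[region_flags]] = True
        if region_flags.any():
            clean[r] = X[idx[~region_flags]].mean(axis=0)
    sizes = np.bincount(partition.region_of[~flags], minlength=g)
    n_out = int(flags.sum())
    logger.info("outlier test: flagged %d of %d cells (alpha=%g)", n_out, X.shape[0], alpha)
    return RegionPartition(
        region_of=partition.region_of,
        centroids=partition.centroids,
        outlier_flag=flags,
        clean_centroids=clean,
        region_sizes=sizes,
    )
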