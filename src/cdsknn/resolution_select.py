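"""Final community detection at the stable K* and label projection.

The L replicate K*NN graphs are clustered with louvain over a resolution
grid; each replicate partition is scored with the Calinski-Harabasz
variance-ratio criterion on that replicate's sampled coordinates.  The
resolution with the highest mean CH wins, the single best-scoring replicate
partition at that resolution becomes the region-level labeling, and every
cell inherits the label of its region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .graph_stability import (
    KnnGraph,
    PartitionLabels,
    SampleMatrix,
    build_knn_graph,
    louvain_cluster,
)
from .io_preprocess import ClusteringResult, EmbeddingMatrix
from .partition import RegionPartition

logger = logging.getLogger(__name__)


@dataclass
class ResolutionScan:
    """CH scores over the resolution grid and the winning partition."""

    grid: list[float]
    ch: np.ndarray                 # (t, L) per-resolution, per-replicate CH
    ch_mean: np.ndarray            # (t,)
    res_star: float
    winning_partition: PartitionLabels  # over the g regions
    winning_replicate: int


def calinski_harabasz(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index [B/(k-1)] / [W/(n-k)].

    B is the size-weighted squared distance of cluster centroids to the
    grand mean, W the within-cluster sum of squares; +inf when W = 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2 or k >= n:
        raise ValueError(f"CH needs 2 <= k < n, got k={k}, n={n}")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for c in range(k):
        pts = X[inv == c]
        centroid = pts.mean(axis=0)
        between += pts.shape[0] * float(((centroid - grand) ** 2).sum())
        within += float(((pts - centroid) ** 2).sum())
    if within == 0.0:
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def resolution_scan(
    graphs: list[KnnGraph],
    samples: list[SampleMatrix],
    grid: list[float],
    seed: int,
) -> ResolutionScan:
    """Sweep the resolution grid over the L replicate K*NN graphs.

    Replicate l is seeded ``seed + l`` (the same stream policy as the
    stability scan).  Degenerate single-community partitions score CH = 0 so
    a too-coarse resolution cannot win by default; if every replicate is
    degenerate at every resolution the scan aborts.
    """
    if len(grid) == 0:
        raise ValueError("resolution grid is empty")
    L = len(graphs)
    t = len(grid)
    ch = np.zeros((t, L))
    parts: list[list[PartitionLabels]] = []
    for ti, res in enumerate(grid):
        row = []
        for l in range(L):
            part = louvain_cluster(graphs[l], resolution=res, seed=seed + l)
            row.append(part)
            if part.n_communities < 2:
                ch[ti, l] = 0.0
                logger.info(
                    "resolution %.3g replicate %d: degenerate partition, CH=0", res, l
                )
            else:
                ch[ti, l] = calinski_harabasz(samples[l].values, part.labels)
        parts.append(row)
    ch_mean = ch.mean(axis=1)
    if not (ch_mean > 0).any():
        raise ValueError(
            "every replicate produced a single community at every resolution; "
            "try a wider resolution grid"
        )
    best_t = int(np.argmax(ch_mean))  # argmax takes the first (smallest res) on ties
    best_l = int(np.argmax(ch[best_t]))
    winning = parts[best_t][best_l]
    logger.info(
        "resolution scan: res*=%.3g (mean CH=%.4g), winning replicate %d with %d communities",
        grid[best_t], ch_mean[best_t], best_l, winning.n_communities,
    )
    return ResolutionScan(
        grid=list(grid),
        ch=ch,
        ch_mean=ch_mean,
        res_star=float(grid[best_t]),
        winning_partition=winning,
        winning_replicate=best_l,
    )


def resolution_scan_at_k(
    stability_samples: list[SampleMatrix],
    k_star: int,
    grid: list[float],
    seed: int,
) -> ResolutionScan:
    """Convenience wrapper: rebuild the L replicate graphs at K* and scan."""
    graphs = [build_knn_graph(s.values, k_star) for s in stability_samples]
    return resolution_scan(graphs, stability_samples, grid, seed)


def finalize_labels(
    scan: ResolutionScan,
    partition: RegionPartition,
    cell_ids: list[str],
    k_star: int,
) -> ClusteringResult:
    """Project the winning region-level partition back to all cells.

    Every cell (outliers included) inherits its region's community id, so
    two cells of the same region always share a final label; outliers keep
    their flag in the output.
    """
    region_labels = scan.winning_partition.labels
    cell_labels = region_labels[partition.region_of]
    n_clusters = int(np.unique(cell_labels).size)
    return ClusteringResult(
        cell_ids=list(cell_ids),
        region_of=partition.region_of.copy(),
        cell_labels=cell_labels,
        is_outlier=partition.outlier_flag.copy(),
        n_clusters=n_clusters,
        k_star=int(k_star),
        res_star=scan.res_star,
    )
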