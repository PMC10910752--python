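"""Evaluation measures: ARI, cluster-count deviation, imbalance ratio,
marker-gene calling and Jaccard similarity of marker sets."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import false_discovery_control, mannwhitneyu
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)


@dataclass
class MarkerSet:
    """Genes passing the fold-change and adjusted-p thresholds for one
    cluster, with the per-gene statistics behind the calls."""

    cluster_id: object
    genes: set[str]
    stats: pd.DataFrame  # columns: gene, log2fc, pval, padj


def adjusted_rand_index(truth, predicted) -> float:
    """Chance-corrected pair-counting agreement between two labelings.

    Computed from the contingency table (sums of C(n_ij, 2)), which equals
    the explicit TP/TN/FP/FN pair-counting definition; 1 for identical
    partitions, ~0 for independent ones.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError(
            f"label vectors differ in length: {truth.shape} vs {predicted.shape}"
        )
    return float(adjusted_rand_score(truth, predicted))


def deviation(estimated_k: int, benchmark_k: int) -> int:
    """Estimated minus benchmark cluster count (positive = overestimate)."""
    if estimated_k < 1 or benchmark_k < 1:
        raise ValueError("cluster counts must be >= 1")
    return int(estimated_k) - int(benchmark_k)


def imbalance_ratio(labels) -> float:
    """Largest cluster size divided by smallest cluster size."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    counts = np.unique(labels, return_counts=True)[1]
    return float(counts.max() / counts.min())


def jaccard(set_a, set_b) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 (logged) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        logger.info("jaccard of two empty sets, returning 0")
        return 0.0
    return len(a & b) / len(union)


def call_markers(
    X,
    gene_ids: list[str],
    labels,
    lfc_min: float = 2.0,
    p_max: float = 0.01,
) -> dict[object, MarkerSet]:
    """One-vs-rest marker genes per cluster.

    ``X`` is a log1p-transformed cells x genes matrix.  Per cluster each
    gene gets a one-sided Wilcoxon rank-sum test (cluster > rest) and
    Benjamini-Hochberg adjustment across genes within the cluster; genes
    with log2 fold change > ``lfc_min`` and adjusted p < ``p_max`` are kept.
    Fold changes compare expm1-ed group means with a pseudocount of 1.
    Single-cell clusters are skipped with a warning.
    """
    X = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("marker calling needs at least 2 clusters")
    out: dict[object, MarkerSet] = {}
    for c in clusters:
        mask = labels == c
        if mask.sum() < 2:
            logger.warning("cluster %r has a single cell; skipped", c)
            continue
        inside, outside = X[mask], X[~mask]
        _, pvals = mannwhitneyu(inside, outside, alternative="greater", axis=0)
        padj = false_discovery_control(pvals, method="bh")
        mean_in = np.expm1(inside.mean(axis=0))
        mean_out = np.expm1(outside.mean(axis=0))
        log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))
        keep = (log2fc > lfc_min) & (padj < p_max)
        stats = pd.DataFrame(
            {"gene": gene_ids, "log2fc": log2fc, "pval": pvals, "padj": padj}
        )
        out[c] = MarkerSet(
            cluster_id=c,
            genes={gene_ids[i] for i in np.flatnonzero(keep)},
            stats=stats,
        )
    return out
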