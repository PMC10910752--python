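"""Stable neighborhood-size selection by resampling and reduced mutual
information.

One non-outlier cell is drawn per region (``L`` replicates), a KNN graph is
built over each replicate for every candidate K, and louvain partitions of
those graphs are compared pairwise with the normalized reduced mutual
information (NRMI).  Reduced mutual information penalizes plain MI by the
log-count of contingency tables sharing the observed community-size
margins,

    RMI(u; v) = I(u; v) - (1/n) log Omega(a, b),

which removes MI's bias toward partitions with many communities.  The K
whose L x L NRMI similarity matrix has the smallest coefficient of
variation is the stable K*.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from functools import lru_cache
from math import lgamma, log

import igraph as ig
import numpy as np
from scipy.spatial.distance import cdist

from .config import RunConfig
from .partition import RegionPartition
from .io_preprocess import EmbeddingMatrix

logger = logging.getLogger(__name__)

#: Margin totals up to this value use the exact dynamic-programming count of
#: contingency tables; larger totals use the analytic estimate.
EXACT_OMEGA_MAX_N = 14


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SampleMatrix:
    """One sampled representative cell per region (rows ordered by region)."""

    values: np.ndarray        # (g, N)
    source_index: np.ndarray  # (g,) cell index sampled for each region
    replicate_id: int


@dataclass
class KnnGraph:
    """Union-symmetrized unweighted K-nearest-neighbor graph."""

    n_vertices: int
    k: int
    edges: np.ndarray   # (m, 2) sorted unique undirected pairs, i < j
    weights: np.ndarray  # (m,) all ones

    def to_igraph(self) -> ig.Graph:
        return ig.Graph(n=self.n_vertices, edges=[tuple(e) for e in self.edges])


@dataclass
class PartitionLabels:
    """Community assignment of graph vertices (ids consecutive from 0)."""

    labels: np.ndarray
    n_communities: int
    resolution: float


@dataclass
class StabilityResult:
    """Per-K NRMI similarity matrices, their CVs and the selected K*."""

    k_grid: list[int]
    similarity: dict[int, np.ndarray]  # K -> (L, L) symmetric, diag 1
    cv: dict[int, float]
    mean_nrmi: dict[int, float]
    k_star: int
    samples: list[SampleMatrix]


# ---------------------------------------------------------------------------
# resampling and graph construction
# ---------------------------------------------------------------------------

def sample_representatives(
    M: EmbeddingMatrix, partition: RegionPartition, replicate_id: int, seed: int
) -> SampleMatrix:
    """Draw one uniformly chosen non-outlier cell per region.

    Deterministic given ``(seed, replicate_id)``; distinct replicate ids give
    independent draws.
    """
    rng = np.random.default_rng([seed % (2**31), replicate_id])
    idx = np.empty(partition.g, dtype=int)
    for r in range(partition.g):
        eligible = partition.members(r, clean=True)
        if eligible.size == 0:
            raise ValueError(f"region {r} has no eligible (non-outlier) cells")
        idx[r] = eligible[rng.integers(eligible.size)]
    return SampleMatrix(
        values=M.values[idx], source_index=idx, replicate_id=replicate_id
    )


def neighbor_order(values: np.ndarray) -> np.ndarray:
    """All-pairs Euclidean neighbor ranking, ties broken by lower index.

    Returns an (n, n-1) matrix whose row i lists the other vertices in
    increasing distance from i.
    """
    n = values.shape[0]
    dist = cdist(values, values)
    np.fill_diagonal(dist, np.inf)
    cols = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((cols, dist), axis=1)  # distance first, index second
    return order[:, : n - 1]


def build_knn_graph(
    values: np.ndarray, k: int, order: np.ndarray | None = None
) -> KnnGraph:
    """Connect each vertex to its ``k`` nearest neighbors (Euclidean, ties to
    the lower vertex index) and symmetrize by edge union; weights are 1."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the vertex count {n}")
    if k < 1:
        raise ValueError("k must be positive")
    if order is None:
        order = neighbor_order(values)
    src = np.repeat(np.arange(n), k)
    dst = order[:, :k].ravel()
    pairs = np.sort(np.column_stack([src, dst]), axis=1)
    edges = np.unique(pairs, axis=0)
    return KnnGraph(n_vertices=n, k=k, edges=edges, weights=np.ones(len(edges)))


def louvain_cluster(graph: KnnGraph, resolution: float, seed: int) -> PartitionLabels:
    """Louvain (multilevel modularity) community detection at the given
    resolution, deterministic for a fixed seed."""
    if graph.n_vertices == 0:
        raise ValueError("empty graph")
    g = graph.to_igraph()
    state = random.getstate()
    try:
        random.seed(seed % (2**31))
        clustering = g.community_multilevel(resolution=float(resolution))
    finally:
        random.setstate(state)
    labels = _consecutive(np.asarray(clustering.membership))
    return PartitionLabels(
        labels=labels,
        n_communities=int(labels.max()) + 1,
        resolution=float(resolution),
    )


def _consecutive(labels: np.ndarray) -> np.ndarray:
    """Relabel community ids to 0..k-1 in order of first appearance."""
    _, first_pos, inv = np.unique(labels, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_pos))
    return order[inv]


# ---------------------------------------------------------------------------
# (reduced) mutual information
# ---------------------------------------------------------------------------

def _contingency(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    u = np.asarray(u)
    v = np.asarray(v)
    if u.shape != v.shape:
        raise ValueError(f"label vectors differ in length: {u.shape} vs {v.shape}")
    _, ui = np.unique(u, return_inverse=True)
    _, vi = np.unique(v, return_inverse=True)
    table = np.zeros((ui.max() + 1, vi.max() + 1), dtype=np.int64)
    np.add.at(table, (ui, vi), 1)
    return table


def mutual_information(u, v) -> float:
    """Mutual information between two partitions in nats:
    I = sum_rs (n_rs/n) ln(n n_rs / (a_r b_s))."""
    u = getattr(u, "labels", u)
    v = getattr(v, "labels", v)
    table = _contingency(u, v)
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    r, s = np.nonzero(table)
    nrs = table[r, s].astype(float)
    return float(np.sum(nrs / n * np.log(n * nrs / (a[r] * b[s].astype(float)))))


def log_omega_exact(a, b) -> float:
    """Exact natural log of the number of nonnegative integer matrices with
    row sums ``a`` and column sums ``b``, by dynamic programming over
    columns.  Practical for totals up to a few tens."""
    a = tuple(int(x) for x in a)
    b = tuple(int(x) for x in b)
    if sum(a) != sum(b):
        raise ValueError(f"margin sums differ: {sum(a)} vs {sum(b)}")
    b_sorted = tuple(sorted(b, reverse=True))

    @lru_cache(maxsize=None)
    def count(rem: tuple, j: int) -> int:
        if j == len(b_sorted):
            return 1  # rem is all zeros by construction
        target = b_sorted[j]

        def compositions(i: int, left: int, cur: tuple) -> int:
            if i == len(rem):
                return count(tuple(sorted(cur, reverse=True)), j + 1) if left == 0 else 0
            total = 0
            hi = min(left, rem[i])
            lo = max(0, left - sum(rem[i + 1:]))
            for x in range(lo, hi + 1):
                total += compositions(i + 1, left - x, cur + (rem[i] - x,))
            return total

        return compositions(0, target, ())

    return log(count(tuple(sorted(a, reverse=True)), 0))


def _log_dirichlet_multinomial(a, c: float) -> float:
    """log pmf of counts ``a`` under a symmetric Dirichlet-multinomial with
    concentration ``c`` per category."""
    n = sum(a)
    k = len(a)
    out = lgamma(n + 1) + lgamma(k * c) - lgamma(n + k * c)
    for ar in a:
        out += lgamma(ar + c) - lgamma(ar + 1) - lgamma(c)
    return out


def _log_omega_conditional(a, b) -> float:
    """Estimate log Omega as (tables with column sums b) x P(row sums = a).

    A uniform table with column sums b has independent uniform column
    compositions, i.e. Dirichlet-multinomial columns with unit
    concentration; the induced row-sum vector is approximated by a symmetric
    Dirichlet-multinomial whose effective concentration matches its
    variance.
    """
    n = sum(a)
    R = len(a)
    log_nb = sum(
        lgamma(bs + R) - lgamma(bs + 1) - lgamma(R) for bs in b
    )  # sum_s log C(b_s + R - 1, R - 1)
    v = sum(bs * (bs + R) for bs in b) / ((R + 1) * n)
    if v <= 1.0 + 1e-12:
        c = 1e9  # every column is a single count: row sums ~ multinomial
    else:
        c = max((n - v) / (R * (v - 1.0)), 1e-9)
    return log_nb + _log_dirichlet_multinomial(a, c)


def log_omega(a, b) -> float:
    """log of the contingency-table count with margins (a, b): exact DP for
    totals <= 14, the symmetrized effective-concentration estimate above it.
    Symmetric under margin swap; 0 whenever either margin has one part."""
    a = tuple(int(x) for x in a)
    b = tuple(int(x) for x in b)
    n = sum(a)
    if n != sum(b):
        raise ValueError(f"margin sums differ: {n} vs {sum(b)}")
    if n < 1:
        raise ValueError("margins must have positive total")
    if len(a) == 1 or len(b) == 1:
        return 0.0
    if n <= EXACT_OMEGA_MAX_N:
        return log_omega_exact(a, b)
    return 0.5 * (_log_omega_conditional(a, b) + _log_omega_conditional(b, a))


def rmi(u, v) -> float:
    """Reduced mutual information in nats:
    RMI = I(u; v) - (1/n) log Omega(a, b).  May be negative."""
    u = np.asarray(getattr(u, "labels", u))
    v = np.asarray(getattr(v, "labels", v))
    if u.shape != v.shape:
        raise ValueError(f"label vectors differ in length: {u.shape} vs {v.shape}")
    n = u.size
    a = tuple(np.bincount(np.unique(u, return_inverse=True)[1]))
    b = tuple(np.bincount(np.unique(v, return_inverse=True)[1]))
    return mutual_information(u, v) - log_omega(a, b) / n


def nrmi(u, v) -> float:
    """Normalized RMI: the cross-RMI divided by the average of the two
    self-RMIs; 1 for identical non-degenerate partitions, 0 (logged) when
    both partitions are degenerate."""
    u = np.asarray(getattr(u, "labels", u))
    v = np.asarray(getattr(v, "labels", v))
    denom = 0.5 * (rmi(u, u) + rmi(v, v))
    if denom <= 0.0:
        logger.info("NRMI: degenerate partitions (denominator <= 0), returning 0")
        return 0.0
    return rmi(u, v) / denom


def coefficient_of_variation(s: np.ndarray) -> float:
    """Sample sd over mean of the strict upper triangle of a similarity
    matrix; +inf when the mean is 0 (so the K can never be selected)."""
    s = np.asarray(s, dtype=float)
    L = s.shape[0]
    if L < 2:
        raise ValueError("similarity matrix needs at least 2 replicates")
    vals = s[np.triu_indices(L, k=1)]
    mean = vals.mean()
    if mean == 0.0:
        return float("inf")
    return float(vals.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# the stability scan
# ---------------------------------------------------------------------------

def stability_scan(
    M: EmbeddingMatrix, partition: RegionPartition, config: RunConfig
) -> StabilityResult:
    """Select the stable neighborhood size K*.

    For each of L replicates one representative per region is sampled and,
    for every K in ``k_min..k_max``, its KNN graph is clustered with louvain
    at ``res_default`` (replicate l seeded as ``seed + l``).  Partitions of
    different replicates share the vertex set of g regions, so their
    pairwise NRMI forms an L x L similarity matrix per K; the K with the
    smallest coefficient of variation wins, ties going to the smaller K.
    """
    L = config.L
    samples = [
        sample_representatives(M, partition, replicate_id=l, seed=config.seed)
        for l in range(L)
    ]
    orders = [neighbor_order(s.values) for s in samples]
    k_grid = list(range(config.k_min, config.k_max + 1))

    similarity: dict[int, np.ndarray] = {}
    cvs: dict[int, float] = {}
    means: dict[int, float] = {}
    for k in k_grid:
        parts = []
        for l in range(L):
            graph = build_knn_graph(samples[l].values, k, order=orders[l])
            parts.append(
                louvain_cluster(graph, config.res_default, seed=config.seed + l)
            )
        s = np.eye(L)
        for i in range(L):
            for j in range(i + 1, L):
                s[i, j] = s[j, i] = nrmi(parts[i], parts[j])
        similarity[k] = s
        cvs[k] = coefficient_of_variation(s)
        means[k] = float(s[np.triu_indices(L, k=1)].mean())

    k_star = min(k_grid, key=lambda k: (cvs[k], k))
    logger.info(
        "stability scan: K*=%d (cv=%.4g, mean NRMI=%.4g) over K in [%d, %d], L=%d",
        k_star, cvs[k_star], means[k_star], config.k_min, config.k_max, L,
    )
    return StabilityResult(
        k_grid=k_grid,
        similarity=similarity,
        cv=cvs,
        mean_nrmi=means,
        k_star=k_star,
        samples=samples,
    )
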