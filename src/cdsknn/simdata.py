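"""Synthetic embeddings with known cluster structure.

Gaussian mixtures in 2-30 dimensions with a controllable cluster count,
imbalance ratio (largest/smallest cluster), centroid separation in units of
the within-cluster standard deviation, and optional injected outliers.
Cluster sizes interpolate geometrically between the largest and smallest so
intermediate clusters are graded rather than bimodal; within-cluster noise
is spherical with unit sigma, which keeps the chi-squared outlier
calibration exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, sqrt

import numpy as np

from .io_preprocess import EmbeddingMatrix

#: Candidate draws per centroid in the best-candidate placement.
_PLACEMENT_CANDIDATES = 64


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of a simulated Gaussian mixture.

    ``separation`` is the expected centroid spacing in units of the
    within-cluster sigma (scaled by sqrt(dims)); ``ir`` the target ratio of
    largest to smallest cluster size.
    """

    n_cells: int
    k: int
    dims: int
    ir: float = 1.0
    separation: float = 8.0
    outlier_frac: float = 0.0
    outlier_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.n_cells < self.k:
            raise ValueError("need n_cells >= k >= 1")
        if not (2 <= self.dims <= 30):
            raise ValueError("dims must lie in 2..30")
        if self.ir < 1.0:
            raise ValueError("imbalance ratio must be >= 1")
        if not (0.0 <= self.outlier_frac < 0.2):
            raise ValueError("outlier_frac must lie in [0, 0.2)")
        if self.outlier_scale < 1.0:
            raise ValueError("outlier_scale must be >= 1")

    @property
    def min_cluster_size(self) -> int:
        return max(self.dims + 3, 10)


def _geometric_sizes(n: int, k: int, ir: float) -> np.ndarray:
    """Integer cluster sizes on a geometric ladder with max/min ~ ir."""
    if k == 1:
        return np.array([n])
    weights = ir ** (-np.arange(k) / (k - 1))
    real = n * weights / weights.sum()
    sizes = np.floor(real).astype(int)
    # distribute the remainder by largest fractional part, sparing the
    # extremes so the realized ratio stays close to the target
    remainder = n - sizes.sum()
    frac = real - np.floor(real)
    if k > 2:
        frac[0] -= 1.0
        frac[-1] -= 1.0
    for i in np.argsort(-frac)[:remainder]:
        sizes[i] += 1
    return sizes


def max_feasible_ir(n: int, k: int, dims: int) -> float:
    """Largest imbalance ratio whose smallest cluster still meets the
    minimum size max(dims + 3, 10), found by bisection."""
    m_min = max(dims + 3, 10)

    def smallest(ir: float) -> float:
        w = ir ** (-np.arange(k) / max(k - 1, 1))
        return n * w[-1] / w.sum()

    if smallest(1.0) < m_min:
        return 0.0
    lo, hi = 1.0, 1.0
    while smallest(hi) >= m_min and hi < 1e9:
        lo, hi = hi, hi * 2
    for _ in range(80):
        mid = (lo + hi) / 2
        lo, hi = (mid, hi) if smallest(mid) >= m_min else (lo, mid)
    return lo


def _place_centroids(k: int, dims: int, separation: float, rng) -> np.ndarray:
    """Spread k centroids on a sphere of radius separation*sqrt(dims)/sqrt(2)
    by best-candidate (farthest-point) sampling, so realized pairwise
    spacing concentrates near separation*sqrt(dims)."""
    if k == 1:
        return np.zeros((1, dims))
    radius = separation * sqrt(dims) / sqrt(2.0)

    def draw(m: int) -> np.ndarray:
        v = rng.normal(size=(m, dims))
        return radius * v / np.linalg.norm(v, axis=1, keepdims=True)

    centroids = [draw(1)[0]]
    for _ in range(k - 1):
        cand = draw(_PLACEMENT_CANDIDATES)
        dmin = np.min(
            np.linalg.norm(cand[:, None, :] - np.asarray(centroids)[None], axis=2),
            axis=1,
        )
        centroids.append(cand[int(np.argmax(dmin))])
    return np.asarray(centroids)


def simulate_mixture(spec: MixtureSpec) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Generate a Gaussian mixture embedding and its true labels.

    Deterministic (bit-identical) given the spec's seed.  Raises if the
    requested imbalance ratio leaves the smallest cluster below the minimum
    size, reporting the maximum feasible ratio.
    """
    sizes = _geometric_sizes(spec.n_cells, spec.k, spec.ir)
    if sizes.min() < spec.min_cluster_size:
        raise ValueError(
            f"ir={spec.ir} infeasible at n={spec.n_cells}, k={spec.k}: smallest "
            f"cluster would have {sizes.min()} < {spec.min_cluster_size} cells "
            f"(maximum feasible ir ~ {max_feasible_ir(spec.n_cells, spec.k, spec.dims):.1f})"
        )
    rng = np.random.default_rng(spec.seed)
    centroids = _place_centroids(spec.k, spec.dims, spec.separation, rng)
    labels = np.repeat(np.arange(spec.k), sizes)
    X = centroids[labels] + rng.normal(size=(spec.n_cells, spec.dims))
    cell_ids = [f"cell_{i + 1:06d}" for i in range(spec.n_cells)]
    M = EmbeddingMatrix(values=X, cell_ids=cell_ids)
    if spec.outlier_frac > 0:
        M, _ = inject_outliers(
            M, labels, spec.outlier_frac, spec.outlier_scale, seed=spec.seed + 1
        )
    return M, labels


def inject_outliers(
    X: EmbeddingMatrix,
    labels,
    frac: float,
    scale: float,
    seed: int,
) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Displace ceil(frac * P) random cells radially from their cluster mean
    to ``scale`` times their original (Mahalanobis) radius; returns the new
    embedding and the outlier mask."""
    if not (0.0 <= frac < 0.2):
        raise ValueError("frac must lie in [0, 0.2)")
    labels = np.asarray(labels)
    values = X.values.copy()
    mask = np.zeros(values.shape[0], dtype=bool)
    n_out = ceil(frac * values.shape[0])
    if n_out == 0:
        return EmbeddingMatrix(values=values, cell_ids=list(X.cell_ids)), mask
    rng = np.random.default_rng(seed)
    chosen = rng.choice(values.shape[0], size=n_out, replace=False)
    for c in np.unique(labels[chosen]):
        centroid = values[labels == c].mean(axis=0)
        sel = chosen[labels[chosen] == c]
        values[sel] = centroid + scale * (values[sel] - centroid)
    mask[chosen] = True
    return EmbeddingMatrix(values=values, cell_ids=list(X.cell_ids)), mask
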