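"""Matrix input/output and PCA reduction.

Supported inputs: Matrix Market expression matrices with ``genes.txt`` /
``barcodes.txt`` sidecars (gene x cell orientation, transposed on load),
dense CSV expression matrices (cells x genes, header row, first column the
cell id), and dense CSV embeddings (cells x features).  Clustering always
runs on an :class:`EmbeddingMatrix`; raw counts are only revisited for
marker calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Cells x genes nonnegative count/expression matrix (sparse allowed)."""

    values: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        p, g = self.values.shape
        if p != len(self.cell_ids) or g != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cell ids x {len(self.gene_ids)} gene ids"
            )
        if len(set(self.cell_ids)) != p:
            raise ValueError("duplicate cell ids")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(data)):
            raise ValueError("expression matrix contains NaN/Inf entries")
        if data.size and data.min() < 0:
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class EmbeddingMatrix:
    """P x N finite numeric matrix on which all geometry is computed."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("embedding must be a 2-D matrix")
        if self.values.shape[1] < 1:
            raise ValueError("embedding needs at least 1 feature")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("cell id count does not match row count")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding contains NaN/Inf entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ClusteringResult:
    """Final per-cell labels plus the selected hyperparameters."""

    cell_ids: list[str]
    region_of: np.ndarray      # 0-based region index per cell
    cell_labels: np.ndarray    # 0-based cluster id per cell
    is_outlier: np.ndarray     # boolean per cell
    n_clusters: int
    k_star: int
    res_star: float
    outlier_policy: str = "inherit-region-label"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, index_col=0)
    except Exception as exc:  # surface the parser's line information
        raise ValueError(f"failed to parse {path}: {exc}") from exc
    if df.isna().any().any():
        bad = int(np.argmax(df.isna().any(axis=1).to_numpy())) + 2  # +header
        raise ValueError(f"{path}: NaN entry near line {bad}")
    return df


def load_matrix(path: str | Path, format: str) -> ExpressionMatrix | EmbeddingMatrix:
    """Load a matrix from disk, preserving on-disk cell order.

    ``format`` is one of ``mtx`` (Matrix Market, gene x cell, with
    ``genes.txt``/``barcodes.txt`` sidecars next to the file), ``csv``
    (dense cells x genes) or ``embedding-csv`` (dense cells x features).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        genes = (path.parent / "genes.txt").read_text().split()
        barcodes = (path.parent / "barcodes.txt").read_text().split()
        mat = sp.csr_matrix(mat.T)  # -> cells x genes
        return ExpressionMatrix(values=mat, cell_ids=barcodes, gene_ids=genes)
    if format == "csv":
        df = _read_csv(path)
        return ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
        )
    if format == "embedding-csv":
        df = _read_csv(path)
        return EmbeddingMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(i) for i in df.index],
        )
    raise ValueError(f"unknown format {format!r}")


def load_labels(path: str | Path) -> np.ndarray:
    """Read a per-cell label file: one label per line, or a two-column
    TSV/CSV whose second column holds the label."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", header=None)
    if df.shape[1] == 1:
        labels = df.iloc[:, 0]
    else:
        first = str(df.iloc[0, 0]).lower()
        if first in {"cell_id", "cell", "barcode", "id"}:  # header row
            df = df.iloc[1:]
        labels = df.iloc[:, 1]
    return labels.astype(str).to_numpy()


def write_result(result: ClusteringResult, path: str | Path) -> None:
    """Write the final labels as a TSV with columns
    ``cell_id, region, cluster, is_outlier`` (region/cluster 1-based)."""
    df = pd.DataFrame(
        {
            "cell_id": result.cell_ids,
            "region": result.region_of + 1,
            "cluster": _canonical_labels(result.cell_labels) + 1,
            "is_outlier": np.where(result.is_outlier, "TRUE", "FALSE"),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_result(path: str | Path) -> pd.DataFrame:
    """Read back a result TSV written by :func:`write_result`."""
    return pd.read_csv(path, sep="\t")


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel arbitrary ids to consecutive 0..k-1 in order of first
    appearance (stable under cell order)."""
    labels = np.asarray(labels)
    _, first_pos, inv = np.unique(labels, return_index=True, return_inverse=True)
    order = np.argsort(np.argsort(first_pos))
    return order[inv]


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

def reduce_pca(X: ExpressionMatrix, n_pcs: int = 5) -> EmbeddingMatrix:
    """Reduce a cells x genes matrix to its top ``n_pcs`` principal-component
    scores.

    Columns are centered but not scaled; components are ordered by
    decreasing explained variance.  The sign of each component is fixed by
    forcing its largest-magnitude gene loading to be positive, so the output
    does not depend on the eigensolver's sign convention.
    """
    if n_pcs < 1:
        raise ValueError("n_pcs must be positive")
    values = X.values.toarray() if sp.issparse(X.values) else np.asarray(X.values)
    values = values.astype(float)
    p, g = values.shape
    if n_pcs > min(p, g):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(P, G)={min(p, g)}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(values)
    # achievable rank check: components beyond the rank carry ~zero variance
    ev = pca.explained_variance_
    tol = max(p, g) * np.finfo(float).eps * max(ev[0], 1.0)
    rank = int(np.sum(ev > tol))
    if rank < n_pcs:
        raise ValueError(
            f"n_pcs={n_pcs} exceeds the achievable rank {rank} of the centered matrix"
        )
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_pcs), np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    logger.info("PCA: reduced %d x %d matrix to %d components", p, g, n_pcs)
    return EmbeddingMatrix(values=scores, cell_ids=list(X.cell_ids))


def log1p_normalize(X: ExpressionMatrix) -> np.ndarray:
    """log1p-transform counts for marker calling (dense cells x genes)."""
    values = X.values.toarray() if sp.issparse(X.values) else np.asarray(X.values)
    return np.log1p(values.astype(float))
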