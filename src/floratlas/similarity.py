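"""Binarization, inter-dataset distances, and kNN-graph geodesics.

The transport solver consumes three matrices: a nuclei × cells linear cost
comparing reference-gene profiles between the two datasets (Euclidean,
Jaccard or Hamming), and two within-dataset geodesic matrices built from
unweighted kNN graphs — hop-count shortest paths rescaled to [0, 1], which
makes the structural term of the fused objective scale-free.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import cdist

from .core_io import ExpressionMatrix

_METRICS = ("euclidean", "jaccard", "hamming")


@dataclasses.dataclass
class DistanceConfig:
    """Metric choice for nucleus–cell reference-profile comparison.

    Jaccard and Hamming operate on binary data, so they force binarization of
    the single-nucleus values; for Euclidean it is optional.
    """

    metric: str = "jaccard"
    binarize_sc: bool = True

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.metric in ("jaccard", "hamming"):
            self.binarize_sc = True


@dataclasses.dataclass
class GeodesicMatrix:
    """Hop-count shortest-path distances on a kNN graph, rescaled to [0, 1]."""

    values: np.ndarray
    k: int
    disconnected: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("geodesic matrix must be square")
        if not np.isfinite(v).all():
            raise ValueError("geodesic matrix must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("geodesic matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValueError("geodesic matrix must have zero diagonal")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("geodesic entries must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def binarize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Call a gene expressed (1) wherever its normalized value exceeds zero."""
    return ExpressionMatrix(
        expr.barcodes, expr.genes, (expr.values > 0).astype(float),
        binary_flag=True,
    )


def pairwise_distance(A: np.ndarray, B: np.ndarray,
                      config: DistanceConfig) -> np.ndarray:
    """|A| × |B| distances between row profiles sharing a column order.

    Jaccard: 1 − |support intersection| / |support union| (0 for two empty
    supports).  Hamming: fraction of differing positions.  Euclidean: ℓ2.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("A and B must be 2-D with matching columns")
    if config.metric == "euclidean":
        return cdist(A, B, metric="euclidean")
    _require_binary(A)
    _require_binary(B)
    if config.metric == "hamming":
        return cdist(A, B, metric="hamming")
    # Jaccard via boolean algebra; define d = 0 when both supports are empty
    # (scipy's 'jaccard' already uses this convention for double zeros).
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - inter / union
    d[union == 0] = 0.0
    return d


def geodesic_distances(rows: np.ndarray, k: int,
                       config: DistanceConfig | None = None) -> GeodesicMatrix:
    """kNN-graph geodesics over row profiles (or 3D coordinates).

    Each node is linked to its ``k`` nearest rows under the base distance
    (self excluded); the directed graph is symmetrized by union; hop-count
    shortest paths are computed; unreachable pairs are filled with
    (max finite hops + 1); the matrix is divided by its maximum.
    """
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    if not 1 <= k < n:
        raise ValueError("k must satisfy 1 <= k < n_rows")
    if config is None or config.metric == "euclidean":
        base = cdist(rows, rows, metric="euclidean")
    else:
        base = pairwise_distance(rows, rows, config)
    np.fill_diagonal(base, np.inf)  # self-excluded
    nbrs = np.argpartition(base, k - 1, axis=1)[:, :k]
    row_idx = np.repeat(np.arange(n), k)
    adj = csr_matrix(
        (np.ones(n * k), (row_idx, nbrs.ravel())), shape=(n, n)
    )
    adj = adj.maximum(adj.T)  # union symmetrization
    hops = shortest_path(adj, method="D", unweighted=True, directed=False)
    unreachable = ~np.isfinite(hops)
    disconnected = bool(unreachable.any())
    if disconnected:
        fill = hops[np.isfinite(hops)].max() + 1.0
        hops[unreachable] = fill
    return GeodesicMatrix(hops / hops.max(), k=k, disconnected=disconnected)


def _require_binary(M: np.ndarray) -> None:
    if not np.isin(np.unique(M), (0.0, 1.0)).all():
        raise ValueError("jaccard/hamming require binary inputs; binarize first")
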