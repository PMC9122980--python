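"""Fused entropic Gromov–Wasserstein assignment of nuclei to spatial cells.

The solver couples two metric-measure spaces — nuclei, with geodesic
distances over a reference-correlated gene space, and spatial cells, with
geodesic distances over 3D positions — while a linear cost compares each
nucleus's reference-gene profile with each cell's binary calls.  The
objective over couplings T (rows: nuclei, columns: cells; uniform marginals
p, q) is

    J(T) = alpha * <M, T>
         + (1 - alpha) * sum_ijkl (Ds_ik - Dt_jl)^2 T_ij T_kl
         - epsilon * H(T)

minimized by iterated linearization of the quadratic term (the square-loss
gradient in its factored form) followed by entropic-scaling (Sinkhorn)
projection onto the coupling polytope, starting from the independent
coupling T = p q^T.  The resulting plan is the probabilistic assignment of
every nucleus to every cell; projecting the full transcriptome through the
column-renormalized plan yields predicted expression per spatial cell.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .core_io import ExpressionMatrix, GeneSet, SpatialMap
from .preprocess import FilterReport
from .similarity import DistanceConfig, GeodesicMatrix, binarize, pairwise_distance


class SolverWarning(UserWarning):
    pass


@dataclasses.dataclass
class OTConfig:
    """Solver parameters.

    alpha
        Weight of the linear reference-gene cost in [0, 1]; 1 - alpha weights
        the structural (Gromov–Wasserstein) term.
    epsilon
        Entropic regularization strength (> 0); larger values give smoother,
        higher-entropy plans and faster Sinkhorn convergence.
    max_iter, tol
        Outer-loop cap and elementwise plan-change stopping tolerance.
    k_source, k_target
        kNN sizes for the nucleus and spatial-cell geodesic graphs.
    top_k_filter
        Nuclei kept per spatial cell by the pre-integration distance filter
        (0 disables).
    plan_scale
        Multiplier applied when exporting the plan (avoids long decimals).
    """

    alpha: float = 0.1
    epsilon: float = 0.05
    max_iter: int = 5000
    tol: float = 1e-9
    k_source: int = 2
    k_target: int = 5
    top_k_filter: int = 50
    plan_scale: float = 1e5
    sinkhorn_max_iter: int = 1000
    sinkhorn_tol: float = 1e-9

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclasses.dataclass
class TransportPlan:
    """Nuclei × cells coupling with its marginals and convergence record."""

    matrix: np.ndarray
    p: np.ndarray
    q: np.ndarray
    n_iter: int = 0
    final_change: float = float("nan")
    converged: bool = True
    scaled: bool = False
    scale_factor: float = 1.0
    row_ids: np.ndarray | None = None
    col_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if (self.matrix < 0).any():
            raise ValueError("transport plan must be non-negative")

    @property
    def shape(self):
        return self.matrix.shape

    def column_normalized(self) -> np.ndarray:
        """Plan with each column rescaled to sum 1 (distribution over nuclei
        given a cell); invariant to any prior global scaling."""
        colsums = self.matrix.sum(axis=0)
        out = np.zeros_like(self.matrix)
        nz = colsums > 0
        out[:, nz] = self.matrix[:, nz] / colsums[nz]
        if not nz.all():
            warnings.warn("some spatial cells receive no transport mass",
                          SolverWarning, stacklevel=2)
        return out


@dataclasses.dataclass
class ReconstructedAtlas:
    """Spatial cells × genes predicted expression."""

    cell_ids: np.ndarray
    genes: np.ndarray
    values: np.ndarray
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.genes)):
            raise ValueError("atlas values must be (n_cells, n_genes)")
        if (self.values < 0).any():
            raise ValueError("atlas values must be non-negative")

    def gene_values(self, gene: str) -> np.ndarray:
        j = int(np.flatnonzero(np.asarray(self.genes, dtype=object) == gene)[0])
        return self.values[:, j]


# ---------------------------------------------------------------------------
# operations


def prefilter_top_k_nuclei(expr: ExpressionMatrix, spatial_map: SpatialMap,
                           config: DistanceConfig, k: int = 50):
    """Keep the union over spatial cells of each cell's k closest nuclei.

    Distances are computed on reference-gene profiles under ``config``;
    nuclei never among any cell's top k are treated as tissue absent from
    the map and removed.  Ties at rank k are all kept.  ``k <= 0`` or
    ``k >= n_nuclei`` disables the filter.
    """
    if k <= 0 or k >= expr.n_nuclei:
        report = FilterReport("top_k_nuclei", 0, [], {"k": k, "disabled": True})
        return expr, report
    ref = expr.subset_genes([str(g) for g in spatial_map.ref_genes])
    profiles = binarize(ref).values if config.binarize_sc else ref.values
    D = pairwise_distance(profiles, spatial_map.ref_expr.astype(float), config)
    keep = np.zeros(expr.n_nuclei, dtype=bool)
    # per cell: all nuclei at distance <= k-th smallest (ties kept)
    kth = np.partition(D, k - 1, axis=0)[k - 1, :]
    keep |= (D <= kth[None, :]).any(axis=1)
    report = FilterReport(
        "top_k_nuclei", int((~keep).sum()), list(expr.barcodes[~keep]),
        {"k": k, "metric": config.metric},
    )
    return expr.subset_nuclei(keep), report


def sinkhorn(cost: np.ndarray, p: np.ndarray, q: np.ndarray, epsilon: float,
             max_iter: int = 1000, tol: float = 1e-9) -> np.ndarray:
    """Entropic OT projection: argmin <C,T> - eps*H(T) s.t. marginals (p, q).

    Multiplicative scaling on the Gibbs kernel K = exp(-C/eps) with a
    log-domain fallback when the kernel underflows.
    """
    cost = np.asarray(cost, dtype=float)
    if not np.isfinite(cost).all():
        raise ValueError("cost matrix contains NaN/Inf")
    K = np.exp(-(cost - cost.min()) / epsilon)
    if (K.sum(axis=1) == 0).any() or (K.sum(axis=0) == 0).any():
        return _sinkhorn_log(cost, p, q, epsilon, max_iter, tol)
    u = np.ones_like(p)
    v = np.ones_like(q)
    for _ in range(max_iter):
        u = p / (K @ v)
        v = q / (K.T @ u)
        if not (np.isfinite(u).all() and np.isfinite(v).all()):
            return _sinkhorn_log(cost, p, q, epsilon, max_iter, tol)
        # after the v-update columns match q exactly; check the rows
        if np.abs(u * (K @ v) - p).max() < tol:
            break
    return u[:, None] * K * v[None, :]


def _sinkhorn_log(cost, p, q, epsilon, max_iter, tol):
    from scipy.special import logsumexp

    logK = -cost / epsilon
    f = np.zeros(len(p))
    g = np.zeros(len(q))
    logp, logq = np.log(p), np.log(q)
    for _ in range(max_iter):
        f = epsilon * (logp - logsumexp((logK + g[None, :] / epsilon), axis=1))
        g_new = epsilon * (
            logq - logsumexp((logK + f[:, None] / epsilon), axis=0)
        )
        if np.abs(g_new - g).max() < tol:
            g = g_new
            break
        g = g_new
    return np.exp(logK + f[:, None] / epsilon + g[None, :] / epsilon)


def fused_gw_map(source_geo: GeodesicMatrix, target_geo: GeodesicMatrix,
                 linear_cost: np.ndarray, config: OTConfig) -> TransportPlan:
    """Solve the fused entropic Gromov–Wasserstein problem.

    ``linear_cost`` is the nuclei × cells reference-profile distance matrix;
    it is max-rescaled to [0, 1] so the linear and structural terms are
    commensurate.  Marginals are uniform.  Each outer iteration linearizes
    the quadratic term at the current plan via its square-loss gradient in
    factored form and re-solves the entropic linear problem with Sinkhorn;
    iteration stops when the elementwise plan change drops below ``tol``.
    """
    M = np.asarray(linear_cost, dtype=float)
    Ds = source_geo.values
    Dt = target_geo.values
    n, m = M.shape
    if Ds.shape[0] != n or Dt.shape[0] != m:
        raise ValueError("geodesic matrices do not match linear cost shape")
    if not np.isfinite(M).all():
        raise ValueError("linear cost contains NaN/Inf")
    if (M < 0).any():
        raise ValueError("linear cost must be non-negative")
    if M.max() > 0:
        M = M / M.max()
    p = np.full(n, 1.0 / n)
    q = np.full(m, 1.0 / m)
    T = np.outer(p, q)
    alpha = config.alpha
    # square-loss gradient constants: with T in the polytope,
    # sum_kl Ds_ik^2 T_kl = (Ds^2 @ p)_i and likewise for the target side
    c_s = (Ds ** 2) @ p
    c_t = (Dt ** 2) @ q
    change = np.inf
    it = 0
    for it in range(1, config.max_iter + 1):
        if alpha == 1.0:
            grad = M
        else:
            quad = c_s[:, None] + c_t[None, :] - 2.0 * (Ds @ T @ Dt)
            grad = alpha * M + (1.0 - alpha) * quad
        T_new = sinkhorn(grad, p, q, config.epsilon,
                         config.sinkhorn_max_iter, config.sinkhorn_tol)
        change = np.abs(T_new - T).max()
        T = T_new
        if change <= config.tol or alpha == 1.0:
            break
    converged = bool(change <= config.tol or alpha == 1.0)
    if not converged:
        warnings.warn(
            f"fused GW did not converge in {config.max_iter} iterations "
            f"(last change {change:.3e})", SolverWarning, stacklevel=2,
        )
    return TransportPlan(T, p, q, n_iter=it, final_change=float(change),
                         converged=converged)


def scale_plan(plan: TransportPlan, factor: float = 1e5) -> TransportPlan:
    """Multiply every plan entry by ``factor`` for export (total mass becomes
    ``factor``); probabilistic consumers renormalize, undoing the scaling."""
    if plan.scaled:
        raise ValueError("plan already scaled")
    return dataclasses.replace(
        plan, matrix=plan.matrix * factor,
        scaled=(factor != 1.0), scale_factor=factor,
    )


def project_expression(plan: TransportPlan, expr: ExpressionMatrix,
                       genes: GeneSet | None = None,
                       cell_ids: np.ndarray | None = None,
                       provenance: dict | None = None) -> ReconstructedAtlas:
    """Predicted expression per spatial cell as a conditional mean.

    Each plan column is renormalized to a distribution over nuclei; the
    prediction for gene g at cell j is the plan-weighted average of g over
    nuclei.  Invariant to plan scaling and to the number of nuclei.
    """
    if plan.shape[0] != expr.n_nuclei:
        raise ValueError("plan rows do not align with expression nuclei")
    sub = expr if genes is None else expr.subset_genes(list(genes))
    That = plan.column_normalized()
    values = That.T @ sub.values
    ids = cell_ids if cell_ids is not None else np.arange(plan.shape[1])
    return ReconstructedAtlas(np.asarray(ids, dtype=object), sub.genes, values,
                              provenance or {})
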