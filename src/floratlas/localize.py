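"""Placing external signatures and nucleus clusters onto the spatial map.

Signature mode correlates a bulk transcriptomic signature (e.g. a sorted
vascular stem-cell population) with every cell's reconstructed profile over
a marker gene set, after log transform and per-gene mean-centering; the
one-sided p-value tests whether the correlation exceeds zero.  Cluster mode
distributes each spatial cell's incoming transport mass over the nucleus
clusters, giving per-cell cluster membership scores that sum to one.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats

from .core_io import ClusterLabels, GeneSet
from .otmap import ReconstructedAtlas, TransportPlan


@dataclasses.dataclass
class LocalizationResult:
    cell_ids: np.ndarray
    mode: str
    r: np.ndarray | None = None
    p: np.ndarray | None = None
    scores: np.ndarray | None = None
    clusters: np.ndarray | None = None
    markers: GeneSet | None = None
    n_genes: int = 0


def signature_localization(atlas: ReconstructedAtlas, signature: dict,
                           markers: GeneSet,
                           n_permutations: int = 0,
                           seed: int | None = None) -> LocalizationResult:
    """Per-cell Pearson correlation of a signature over marker genes.

    Both the atlas (per cell) and the signature are log2(x+1)-transformed
    and per-gene mean-centered before correlating.  p-values come from the
    exact t transform t = r*sqrt(n-2)/sqrt(1-r^2), upper tail, df = n-2;
    optionally a gene-label permutation p-value is computed instead.
    """
    atlas_genes = set(map(str, atlas.genes))
    shared = [g for g in markers if g in atlas_genes and g in signature]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared marker genes")
    idx = [int(np.flatnonzero(np.asarray(atlas.genes, dtype=object) == g)[0])
           for g in shared]
    X = np.log2(atlas.values[:, idx] + 1.0)
    X = X - X.mean(axis=0)  # center each gene across cells
    s = np.log2(np.array([signature[g] for g in shared], dtype=float) + 1.0)
    s = s - s.mean()
    n = len(shared)
    Xc = X - X.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(sc)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ sc) / denom
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(r)
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            rp = (Xc @ sc[perm]) / denom
            exceed += rp >= r
        p = (1.0 + exceed) / (1.0 + n_permutations)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
        p = stats.t.sf(t, df=n - 2)
        p[r >= 1.0] = 0.0  # exact-match limit
        p[r <= -1.0] = 1.0
    return LocalizationResult(atlas.cell_ids, "signature", r=r, p=p,
                              markers=GeneSet(shared), n_genes=n)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def cluster_localization(plan: TransportPlan,
                         labels: ClusterLabels) -> LocalizationResult:
    """Per-cell cluster membership scores from the transport plan.

    Columns of the plan are normalized to sum 1; the score of spatial cell j
    for cluster c is the summed (normalized) probability of the nuclei in c.
    Nuclei without a label are grouped as "unassigned".  Scores per cell sum
    to 1; cells receiving no mass score NaN with a warning.
    """
    if plan.row_ids is None:
        raise ValueError("plan carries no nucleus identifiers")
    That = plan.column_normalized()
    lab = labels.labels_for(plan.row_ids)
    clusters = np.array(sorted(set(lab), key=str), dtype=object)
    scores = np.vstack([That[lab == c].sum(axis=0) for c in clusters]).T
    empty = plan.matrix.sum(axis=0) == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} spatial cells receive no mass; "
                      "their scores are NaN", UserWarning, stacklevel=2)
        scores[empty] = np.nan
    cell_ids = plan.col_ids if plan.col_ids is not None else np.arange(
        plan.shape[1])
    return LocalizationResult(np.asarray(cell_ids, dtype=object), "clusters",
                              scores=scores, clusters=clusters)
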