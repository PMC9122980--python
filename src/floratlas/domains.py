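"""Expression domains on the reconstructed atlas.

Cells of the reconstructed organ are grouped into expression domains by
average-linkage hierarchical clustering of log-standardized profiles over a
set of reliably predicted, spatially variable genes (PEP above threshold,
variance above threshold).  Downstream summaries quantify per-domain mean
expression, expression inside reference-gene-positive (homeotic) domains,
temporal fold-changes between two time points mapped onto the same
reference, and relative expression of gene signatures in external samples.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .core_io import GeneSet, SpatialMap, standardize
from .otmap import ReconstructedAtlas
from .validate import PEPTable


@dataclasses.dataclass
class DomainAssignment:
    """cell → domain label in {1..k}, labels ordered by decreasing size."""

    labels: np.ndarray
    k: int
    genes: GeneSet
    parameters: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(np.unique(self.labels)) > self.k:
            raise ValueError("more distinct labels than k")


@dataclasses.dataclass
class DomainExpressionTable:
    """domain × gene mean expression plus per-domain cell counts."""

    domains: np.ndarray
    genes: np.ndarray
    means: np.ndarray
    counts: np.ndarray

    def row(self, domain: int) -> np.ndarray:
        return self.means[int(np.flatnonzero(self.domains == domain)[0])]


def select_domain_genes(atlas: ReconstructedAtlas, pep: PEPTable,
                        pep_min: float = 0.13, var_min: float = 3.0) -> GeneSet:
    """Genes with PEP > ``pep_min`` and predicted-expression variance >
    ``var_min`` (both strict)."""
    var = atlas.values.var(axis=0)
    chosen = [
        str(g) for g, v in zip(atlas.genes, var)
        if not math.isnan(pep.scores.get(str(g), float("nan")))
        and pep.scores[str(g)] > pep_min and v > var_min
    ]
    if not chosen:
        raise ValueError(
            "no gene passes PEP/variance thresholds; lower pep_min or var_min")
    return GeneSet(chosen)


def standardize_log(atlas: ReconstructedAtlas, genes: GeneSet) -> np.ndarray:
    """log2(x+1) then per-gene z-score (population sd; constant genes → 0)."""
    idx = [int(np.flatnonzero(np.asarray(atlas.genes, dtype=object) == g)[0])
           for g in genes]
    return standardize(np.log2(atlas.values[:, idx] + 1.0))


def cluster_domains(standardized: np.ndarray, k: int = 15,
                    method: str = "average", metric: str = "euclidean",
                    genes: GeneSet = GeneSet([])) -> DomainAssignment:
    """Cut an average-linkage Euclidean dendrogram into exactly k domains."""
    standardized = np.asarray(standardized, dtype=float)
    n = standardized.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of cells")
    if k == n:
        raw = np.arange(1, n + 1)
    else:
        Z = linkage(pdist(standardized, metric=metric), method=method)
        raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber labels by decreasing cluster size (ties by first occurrence)
    uniq, counts = np.unique(raw, return_counts=True)
    order = uniq[np.argsort(-counts, kind="stable")]
    remap = {int(old): new for new, old in enumerate(order, start=1)}
    labels = np.array([remap[int(v)] for v in raw])
    return DomainAssignment(labels, k, genes,
                            {"method": method, "metric": metric})


def domain_means(atlas: ReconstructedAtlas,
                 assignment: DomainAssignment) -> DomainExpressionTable:
    """Arithmetic mean per domain per gene on the untransformed atlas."""
    if len(assignment.labels) != len(atlas.cell_ids):
        raise ValueError("assignment does not cover the atlas cells")
    domains = np.arange(1, assignment.k + 1)
    means = np.full((len(domains), atlas.values.shape[1]), np.nan)
    counts = np.zeros(len(domains), dtype=int)
    for i, d in enumerate(domains):
        mask = assignment.labels == d
        counts[i] = int(mask.sum())
        if counts[i] == 0:
            warnings.warn(f"domain {d} is empty", UserWarning, stacklevel=2)
            continue
        means[i] = atlas.values[mask].mean(axis=0)
    return DomainExpressionTable(domains, np.asarray(atlas.genes, dtype=object),
                                 means, counts)


def homeotic_domain_expression(atlas: ReconstructedAtlas,
                               spatial_map: SpatialMap,
                               ref_genes: str | tuple) -> dict:
    """Mean predicted expression over cells positive for the named reference
    gene(s) — e.g. the AP3- or AG-positive whorl domain; a pair requires both
    calls positive."""
    if isinstance(ref_genes, str):
        ref_genes = (ref_genes,)
    mask = np.ones(spatial_map.n_cells, dtype=bool)
    for g in ref_genes:
        j = int(np.flatnonzero(spatial_map.ref_genes == g)[0])
        mask &= spatial_map.ref_expr[:, j] == 1
    if not mask.any():
        raise ValueError(f"no cell positive for {ref_genes}")
    means = atlas.values[mask].mean(axis=0)
    return {str(g): float(v) for g, v in zip(atlas.genes, means)}


def domain_log2_fold_change(means_a: dict, means_b: dict,
                            pseudocount: float = 1.0) -> dict:
    """log2((a + pc) / (b + pc)) per shared gene."""
    return {
        g: float(np.log2((means_a[g] + pseudocount)
                         / (means_b[g] + pseudocount)))
        for g in means_a if g in means_b
    }


def temporal_fold_change(table_a: DomainExpressionTable,
                         table_b: DomainExpressionTable,
                         lfc_min: float = 1.0,
                         pseudocount: float = 1.0) -> dict:
    """Per-domain up/down gene lists between two time points.

    Both tables must come from atlases mapped onto the same spatial
    reference with identical domain labels.  A gene is "up" in a domain when
    log2((meanA + pc)/(meanB + pc)) > lfc_min (strict), "down" when below
    -lfc_min.
    """
    if (not np.array_equal(table_a.domains, table_b.domains)
            or not np.array_equal(table_a.genes, table_b.genes)):
        raise ValueError("domain/gene labels of the two tables do not match")
    out = {}
    with np.errstate(invalid="ignore"):
        lfc = np.log2((table_a.means + pseudocount)
                      / (table_b.means + pseudocount))
    for i, d in enumerate(table_a.domains):
        row = lfc[i]
        genes = table_a.genes
        out[int(d)] = {
            "up": [str(g) for g, v in zip(genes, row) if v > lfc_min],
            "down": [str(g) for g, v in zip(genes, row) if v < -lfc_min],
        }
    return out


def signature_relative_expression(gene_list: GeneSet, external_expr: dict,
                                  background: GeneSet) -> dict:
    """Per-sample median of ``gene_list`` minus median of ``background``.

    ``external_expr`` maps gene → per-sample value vector (all vectors the
    same length; e.g. expression in mature organ samples).
    """
    sig = [g for g in gene_list if g in external_expr]
    bg = [g for g in background if g in external_expr]
    if not sig or not bg:
        raise ValueError("gene list/background do not intersect the table")
    sig_m = np.median(np.array([external_expr[g] for g in sig], dtype=float),
                      axis=0)
    bg_m = np.median(np.array([external_expr[g] for g in bg], dtype=float),
                     axis=0)
    return {"relative_median": sig_m - bg_m, "n_signature": len(sig),
            "n_background": len(bg)}


def relative_expression(values: np.ndarray) -> np.ndarray:
    """Center each gene (row) by its mean across groups/samples."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a gene × group matrix with >= 2 groups")
    return values - values.mean(axis=1, keepdims=True)
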