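"""Filtering rules applied before integration.

The spatial map keeps only cells that are informative anchors: cells must
express at least one reference gene, at least ``min_genes`` of them, and
carry a binary reference pattern shared with enough other cells that the
pattern is trustworthy.  Reference genes that are constant across the map or
absent from the single-nucleus data carry no integration signal and are
dropped.  On the single-nucleus side, rarely detected genes and nuclei that
express none of the surviving reference genes are removed, and the gene set
used for the nucleus–nucleus distance graph is chosen by correlation to the
reference panel.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import ExpressionMatrix, GeneSet, SpatialMap


class EmptyResultError(ValueError):
    """A filter removed every item."""


@dataclasses.dataclass
class FilterReport:
    stage: str
    items_removed: int
    item_ids: list
    parameters: dict

    def __post_init__(self) -> None:
        self.item_ids = list(self.item_ids)
        if self.items_removed != len(self.item_ids):
            raise ValueError("items_removed must equal len(item_ids)")


def filter_cells_no_reference(spatial_map: SpatialMap):
    """Drop cells expressing none of the reference genes."""
    keep = spatial_map.ref_expr.sum(axis=1) > 0
    if not keep.any():
        raise EmptyResultError("empty spatial map: no cell expresses any reference gene")
    report = FilterReport(
        "cells_no_reference", int((~keep).sum()),
        list(spatial_map.cell_ids[~keep]), {},
    )
    return spatial_map.subset_cells(keep), report


def filter_uninformative_reference_genes(spatial_map: SpatialMap,
                                         expr: ExpressionMatrix,
                                         scope: str = "map"):
    """Drop reference genes constant across the map or absent from ``expr``.

    ``scope`` selects where constancy is evaluated: ``"map"`` (default) uses
    the spatial map's binary calls, ``"nuclei"`` the single-nucleus values.
    """
    present = np.isin(spatial_map.ref_genes.astype(str), expr.genes.astype(str))
    if scope == "map":
        col = spatial_map.ref_expr
        constant = np.array([len(np.unique(col[:, j])) == 1
                             for j in range(col.shape[1])])
    elif scope == "nuclei":
        constant = np.zeros(spatial_map.n_ref_genes, dtype=bool)
        for j, g in enumerate(spatial_map.ref_genes):
            if present[j]:
                v = expr.values[:, expr.gene_index([g])[0]]
                constant[j] = len(np.unique(v)) == 1
    else:
        raise ValueError(f"unknown scope {scope!r}")
    keep = present & ~constant
    if not keep.any():
        raise EmptyResultError("all reference genes removed")
    removed = [g for g, k in zip(spatial_map.ref_genes, keep) if not k]
    report = FilterReport("uninformative_reference_genes", len(removed),
                          removed, {"scope": scope})
    return spatial_map.subset_genes(list(spatial_map.ref_genes[keep])), report


def filter_sparse_and_rare_combination_cells(spatial_map: SpatialMap,
                                             min_genes: int = 3,
                                             min_combo_support: int = 4):
    """Drop cells with few expressed reference genes or a rare binary pattern.

    A cell is removed when it expresses fewer than ``min_genes`` reference
    genes, or when fewer than ``min_combo_support`` OTHER cells share its
    exact binary pattern.  Both conditions are evaluated on the state at
    entry (no cascading within the step).
    """
    expr = spatial_map.ref_expr
    enough = expr.sum(axis=1) >= min_genes
    patterns, inverse, counts = np.unique(
        expr, axis=0, return_inverse=True, return_counts=True
    )
    supported = (counts[inverse] - 1) >= min_combo_support
    keep = enough & supported
    if not keep.any():
        raise EmptyResultError("empty spatial map after sparsity/rarity filter")
    report = FilterReport(
        "sparse_and_rare_combination_cells", int((~keep).sum()),
        list(spatial_map.cell_ids[~keep]),
        {"min_genes": min_genes, "min_combo_support": min_combo_support},
    )
    return spatial_map.subset_cells(keep), report


def filter_low_prevalence_genes(expr: ExpressionMatrix, min_cells: int = 30,
                                always_keep: GeneSet | None = None):
    """Drop genes detected (nonzero) in fewer than ``min_cells`` nuclei.

    Genes in ``always_keep`` are retained regardless of prevalence.
    """
    protected = set(always_keep or ())
    n_pos = (expr.values > 0).sum(axis=0)
    keep = (n_pos >= min_cells) | np.array(
        [g in protected for g in expr.genes], dtype=bool
    )
    removed = [g for g, k in zip(expr.genes, keep) if not k]
    report = FilterReport(
        "low_prevalence_genes", len(removed), removed,
        {"min_cells": min_cells, "always_keep": sorted(protected)},
    )
    return expr.subset_genes(list(expr.genes[keep])), report


def filter_nuclei_no_reference(expr: ExpressionMatrix, spatial_map: SpatialMap):
    """Drop nuclei expressing none of the map's (final) reference genes."""
    shared = [g for g in spatial_map.ref_genes if g in set(expr.genes)]
    if not shared:
        raise EmptyResultError("no reference gene shared with the expression matrix")
    idx = expr.gene_index(shared)
    keep = (expr.values[:, idx] > 0).any(axis=1)
    if not keep.any():
        raise EmptyResultError("empty result: no nucleus expresses a reference gene")
    report = FilterReport(
        "nuclei_no_reference", int((~keep).sum()),
        list(expr.barcodes[~keep]), {"reference_genes": list(map(str, shared))},
    )
    return expr.subset_nuclei(keep), report


def select_reference_correlated_genes(expr: ExpressionMatrix,
                                      spatial_map: SpatialMap,
                                      top_n: int = 100) -> GeneSet:
    """Union of the top-``top_n`` Pearson-correlated genes per reference gene.

    For each reference gene, every gene in ``expr`` is ranked by Pearson
    correlation (across nuclei) with that reference gene's single-nucleus
    expression; the per-reference top lists are unioned.  Constant genes have
    undefined correlation and are scored 0.  Ties at the boundary break by
    gene id for determinism.
    """
    ref_genes = [str(g) for g in spatial_map.ref_genes]
    missing = [g for g in ref_genes if g not in set(expr.genes)]
    if missing:
        raise KeyError(f"reference genes absent from expression data: {missing}")
    X = expr.values
    Xc = X - X.mean(axis=0)
    sd = X.std(axis=0)
    selected: set = set()
    order = np.argsort(expr.genes.astype(str), kind="stable")
    for g in ref_genes:
        r_idx = expr.gene_index([g])[0]
        ref = Xc[:, r_idx]
        ref_sd = sd[r_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = (Xc.T @ ref) / (len(ref) * sd * ref_sd)
        corr[~np.isfinite(corr)] = 0.0
        # stable sort over id-sorted genes -> lexicographic tie-break
        ranked = order[np.argsort(-corr[order], kind="stable")]
        selected.update(expr.genes[ranked[:top_n]])
    return GeneSet(sorted(selected))
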