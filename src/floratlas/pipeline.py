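"""End-to-end reconstruction: filters → distances → transport → projection.

``reconstruct`` is the high-level entry point used by the CLI and the
validation routines.  ``integrate`` is the inner step shared with
leave-one-gene-out evaluation, which repeats the integration with one
reference gene withheld while keeping the filtered universe fixed.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import preprocess
from .core_io import ExpressionMatrix, GeneSet, SpatialMap
from .otmap import (OTConfig, ReconstructedAtlas, TransportPlan, fused_gw_map,
                    prefilter_top_k_nuclei, project_expression)
from .similarity import DistanceConfig, binarize, geodesic_distances, pairwise_distance


@dataclasses.dataclass
class ReconstructionResult:
    atlas: ReconstructedAtlas
    plan: TransportPlan
    spatial_map: SpatialMap
    expr: ExpressionMatrix
    selected_genes: GeneSet
    reports: list


def apply_spatial_filters(spatial_map: SpatialMap, expr: ExpressionMatrix,
                          min_genes: int = 3, min_combo_support: int = 4,
                          gene_scope: str = "map"):
    """The three spatial-map filters, in order."""
    reports = []
    spatial_map, r = preprocess.filter_cells_no_reference(spatial_map)
    reports.append(r)
    spatial_map, r = preprocess.filter_uninformative_reference_genes(
        spatial_map, expr, scope=gene_scope)
    reports.append(r)
    spatial_map, r = preprocess.filter_sparse_and_rare_combination_cells(
        spatial_map, min_genes=min_genes, min_combo_support=min_combo_support)
    reports.append(r)
    return spatial_map, reports


def apply_expression_filters(expr: ExpressionMatrix, spatial_map: SpatialMap,
                             min_cells: int = 30,
                             always_keep: GeneSet | None = None):
    reports = []
    expr, r = preprocess.filter_low_prevalence_genes(
        expr, min_cells=min_cells, always_keep=always_keep)
    reports.append(r)
    expr, r = preprocess.filter_nuclei_no_reference(expr, spatial_map)
    reports.append(r)
    return expr, reports


def integrate(expr: ExpressionMatrix, spatial_map: SpatialMap,
              selected_genes: GeneSet, ot: OTConfig, dist: DistanceConfig,
              project_genes: GeneSet | None = None):
    """Prefilter nuclei, build cost matrices, solve, project.

    ``spatial_map`` may have a reference gene withheld; ``selected_genes``
    (the nucleus-graph gene space) is supplied by the caller so the evaluated
    universe stays constant across leave-one-out runs.
    """
    expr_f, prefilter_report = prefilter_top_k_nuclei(
        expr, spatial_map, dist, k=ot.top_k_filter)
    ref_genes = [str(g) for g in spatial_map.ref_genes]
    ref_profiles = expr_f.subset_genes(ref_genes)
    if dist.binarize_sc:
        ref_profiles = binarize(ref_profiles)
    linear_cost = pairwise_distance(
        ref_profiles.values, spatial_map.ref_expr.astype(float), dist)
    source_geo = geodesic_distances(
        expr_f.subset_genes(list(selected_genes)).values, k=ot.k_source)
    target_geo = geodesic_distances(spatial_map.coords, k=ot.k_target)
    plan = fused_gw_map(source_geo, target_geo, linear_cost, ot)
    plan = dataclasses.replace(plan, row_ids=expr_f.barcodes,
                               col_ids=spatial_map.cell_ids)
    atlas = project_expression(
        plan, expr_f, genes=project_genes, cell_ids=spatial_map.cell_ids,
        provenance={"ot": dataclasses.asdict(ot),
                    "dist": dataclasses.asdict(dist)},
    )
    return atlas, plan, expr_f, prefilter_report


def reconstruct(expr: ExpressionMatrix, spatial_map: SpatialMap,
                ot: OTConfig | None = None,
                dist: DistanceConfig | None = None,
                min_cells: int = 30, always_keep: GeneSet | None = None,
                min_genes: int = 3, min_combo_support: int = 4,
                top_corr_genes: int = 100,
                project_genes: GeneSet | None = None) -> ReconstructionResult:
    """Full pipeline from raw inputs to a reconstructed atlas."""
    ot = ot or OTConfig()
    dist = dist or DistanceConfig()
    reports = []
    expr, r = preprocess.filter_low_prevalence_genes(
        expr, min_cells=min_cells, always_keep=always_keep)
    reports.append(r)
    spatial_map, map_reports = apply_spatial_filters(
        spatial_map, expr, min_genes=min_genes,
        min_combo_support=min_combo_support)
    reports.extend(map_reports)
    expr, r = preprocess.filter_nuclei_no_reference(expr, spatial_map)
    reports.append(r)
    selected = preprocess.select_reference_correlated_genes(
        expr, spatial_map, top_n=top_corr_genes)
    atlas, plan, expr_f, prefilter_report = integrate(
        expr, spatial_map, selected, ot, dist, project_genes=project_genes)
    reports.append(prefilter_report)
    return ReconstructionResult(atlas, plan, spatial_map, expr_f, selected,
                                reports)
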