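"""Validation of reconstructed atlases.

Performance is measured without any external ground truth by leave-one-out
over the reference panel: each reference gene is withheld from the map, the
integration is rerun, the gene's single-nucleus expression is projected onto
the cells, and the prediction is scored against the gene's known binary
pattern with the AUROC.  The PEP score (predicted estimation performance) —
the maximum Spearman correlation of a gene with any other reference gene in
the nucleus data — predicts this per-gene AUROC without using the map at
all, which makes it usable for prioritizing genes and designing reference
panels.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
from scipy import stats

from .core_io import ExpressionMatrix, GeneSet, SpatialMap
from .otmap import OTConfig
from .pipeline import integrate
from .preprocess import select_reference_correlated_genes
from .similarity import DistanceConfig

#: Reference genes excluded from the summary average by default: genes whose
#: expressing cells share no other reference gene (AHP6, ETT/ARF3, CLV3) or
#: that mark too few cells (WUS).
DEFAULT_EXCLUDE = GeneSet(["AHP6", "ETT", "CLV3", "WUS"])


class ValidationWarning(UserWarning):
    pass


@dataclasses.dataclass
class ValidationReport:
    per_gene: dict
    excluded: tuple
    parameters: dict = dataclasses.field(default_factory=dict)

    @property
    def average(self) -> float:
        vals = [v for g, v in self.per_gene.items()
                if g not in self.excluded and not math.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")


@dataclasses.dataclass
class PEPTable:
    scores: dict
    reference: GeneSet
    n_nuclei: int

    def __getitem__(self, gene: str) -> float:
        return self.scores[gene]


def auroc(scores, labels) -> float:
    """Area under the ROC curve as the Mann–Whitney probability.

    Equals (#positive–negative pairs with score_pos > score_neg + half the
    ties) / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    neg = labels == 0
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    ranks = stats.rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def loocv_reference_genes(expr: ExpressionMatrix, spatial_map: SpatialMap,
                          ot: OTConfig, dist: DistanceConfig,
                          exclude: GeneSet = DEFAULT_EXCLUDE,
                          selected_genes: GeneSet | None = None,
                          ) -> ValidationReport:
    """Leave-one-reference-gene-out AUROC.

    ``expr`` and ``spatial_map`` must already be filtered (the evaluated
    universe of nuclei and cells is held fixed; only the integration step
    excludes the withheld gene).  For each reference gene the linear cost
    and nucleus prefilter are rebuilt from the map minus that gene.
    """
    if selected_genes is None:
        selected_genes = select_reference_correlated_genes(expr, spatial_map)
    per_gene: dict = {}
    for j, gene in enumerate(map(str, spatial_map.ref_genes)):
        truth = spatial_map.ref_expr[:, j]
        if len(np.unique(truth)) < 2:
            warnings.warn(f"{gene}: truth column constant, AUROC undefined",
                          ValidationWarning, stacklevel=2)
            per_gene[gene] = float("nan")
            continue
        reduced = spatial_map.drop_gene(gene)
        atlas, _, _, _ = integrate(expr, reduced, selected_genes, ot, dist,
                                   project_genes=GeneSet([gene]))
        per_gene[gene] = auroc(atlas.gene_values(gene), truth)
    return ValidationReport(
        per_gene, tuple(exclude),
        {"ot": dataclasses.asdict(ot), "dist": dataclasses.asdict(dist)},
    )


def pep_scores(expr: ExpressionMatrix, reference: GeneSet) -> PEPTable:
    """Max Spearman correlation of each gene with any OTHER reference gene.

    Computed on the (post-prefilter) nucleus matrix with average ranks for
    ties.  Constant genes have undefined correlation and score NaN.
    """
    ref = [g for g in reference if g in set(expr.genes)]
    if not ref:
        raise KeyError("no reference gene present in the expression matrix")
    R = np.apply_along_axis(stats.rankdata, 0, expr.values)
    Rc = R - R.mean(axis=0)
    sd = Rc.std(axis=0)
    ref_idx = expr.gene_index(ref)
    n = expr.n_nuclei
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (Rc.T @ Rc[:, ref_idx]) / (n * np.outer(sd, sd[ref_idx]))
    scores: dict = {}
    for i, g in enumerate(map(str, expr.genes)):
        row = corr[i].copy()
        for jr, rg in enumerate(ref):
            if rg == g:
                row[jr] = np.nan  # exclude self-correlation
        row = row[np.isfinite(row)]
        scores[g] = float(row.max()) if row.size else float("nan")
    return PEPTable(scores, GeneSet(ref), n)


def pep_threshold(pep: PEPTable, report: ValidationReport, bins: int = 10,
                  default: float = 0.13, allow_default: bool = True) -> float:
    """PEP value above which predictions become better than chance.

    Reference genes are sorted by PEP, binned, and the smallest PEP of the
    first bin whose mean AUROC exceeds 0.5 — with every later bin also above
    0.5 — is returned.  When the binned curve never crosses and stays above
    0.5, the configured default is returned with a warning.
    """
    usable = [(pep.scores[g], report.per_gene[g]) for g in pep.reference
              if g in report.per_gene
              and not math.isnan(pep.scores[g])
              and not math.isnan(report.per_gene[g])]
    if len(usable) < 3:
        if allow_default:
            warnings.warn("fewer than 3 usable reference genes; returning "
                          "default PEP threshold", ValidationWarning,
                          stacklevel=2)
            return default
        raise ValueError("fewer than 3 reference genes with both PEP and AUROC")
    usable.sort()
    peps = np.array([u[0] for u in usable])
    aucs = np.array([u[1] for u in usable])
    bins = min(bins, len(usable))
    bin_peps = np.array_split(peps, bins)
    bin_means = np.array([a.mean() for a in np.array_split(aucs, bins)])
    above = bin_means > 0.5
    for b in range(bins):
        if above[b:].all():
            return float(bin_peps[b].min())
    warnings.warn("binned AUROC never stabilizes above 0.5; returning default "
                  "PEP threshold", ValidationWarning, stacklevel=2)
    return default


def sequential_elimination(expr: ExpressionMatrix, spatial_map: SpatialMap,
                           ot: OTConfig, dist: DistanceConfig,
                           order: str = "desc",
                           selected_genes: GeneSet | None = None,
                           max_steps: int | None = None,
                           loocv: ValidationReport | None = None) -> list:
    """AUROC trajectory as reference genes are removed from the map.

    Removal order is by the gene's maximum Spearman correlation to the other
    reference genes (``desc``: most-correlated first, which degrades the
    removed genes' PEP fastest; ``asc``: least-correlated first).  Step 0 is
    the leave-one-out result; at step s the first s genes in order are
    withheld together and each withheld gene is scored against its binary
    truth after a single integration on the reduced map.
    Returns a list of dicts: step, removed, per_gene AUROC, mean_auroc.
    """
    if order not in ("desc", "asc"):
        raise ValueError("order must be 'desc' or 'asc'")
    ref_genes = [str(g) for g in spatial_map.ref_genes]
    if len(ref_genes) < 3:
        raise ValueError("need at least 3 reference genes")
    if selected_genes is None:
        selected_genes = select_reference_correlated_genes(expr, spatial_map)
    ref_pep = pep_scores(expr.subset_genes(ref_genes), GeneSet(ref_genes))
    ranked = sorted(ref_genes, key=lambda g: (ref_pep.scores[g], g),
                    reverse=(order == "desc"))
    if loocv is None:
        loocv = loocv_reference_genes(expr, spatial_map, ot, dist,
                                      exclude=GeneSet([]),
                                      selected_genes=selected_genes)
    trajectory = [{
        "step": 0, "removed": [],
        "per_gene": dict(loocv.per_gene),
        "mean_auroc": loocv.average,
    }]
    n_steps = len(ref_genes) - 1 if max_steps is None else min(
        max_steps, len(ref_genes) - 1)
    for s in range(1, n_steps + 1):
        removed = ranked[:s]
        reduced = spatial_map
        for g in removed:
            reduced = reduced.drop_gene(g)
        atlas, _, _, _ = integrate(expr, reduced, selected_genes, ot, dist,
                                   project_genes=GeneSet(removed))
        per_gene = {}
        for g in removed:
            truth = spatial_map.ref_expr[:, ref_genes.index(g)]
            if len(np.unique(truth)) < 2:
                per_gene[g] = float("nan")
                continue
            per_gene[g] = auroc(atlas.gene_values(g), truth)
        vals = [v for v in per_gene.values() if not math.isnan(v)]
        trajectory.append({
            "step": s, "removed": list(removed), "per_gene": per_gene,
            "mean_auroc": float(np.mean(vals)) if vals else float("nan"),
        })
    return trajectory


def pseudobulk_correlation(expr: ExpressionMatrix, bulk: dict) -> float:
    """Pearson R between the pooled nucleus profile and a bulk profile.

    Nuclei are pooled by summing per gene; both vectors are log2(x+1)
    transformed; R is computed over the shared genes (>= 3 required).
    """
    shared = [g for g in expr.genes if g in bulk]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    idx = expr.gene_index(shared)
    pooled = np.log2(expr.values[:, idx].sum(axis=0) + 1.0)
    bulk_v = np.log2(np.array([bulk[g] for g in shared], dtype=float) + 1.0)
    r, _ = stats.pearsonr(pooled, bulk_v)
    return float(r)
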