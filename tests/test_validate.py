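"""AUROC, PEP scores, thresholds, and pseudobulk agreement."""

import math

import numpy as np
import pytest
from scipy import stats

import floratlas as fa
from floratlas import validate as V


def _brute_force_auroc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuroc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ((0.9, 0.8, 0.2, 0.1), (1, 1, 0, 0), 1.0),
        ((0.9, 0.8, 0.2, 0.1), (0, 0, 1, 1), 0.0),
        ((0.9, 0.6, 0.4, 0.2), (1, 0, 1, 0), 0.75),
    ])
    def test_known_values(self, scores, labels, expected):
        assert V.auroc(scores, labels) == pytest.approx(expected)

    def test_matches_pair_enumeration_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(4, 51)
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert V.auroc(scores, labels) == pytest.approx(
                _brute_force_auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            V.auroc([0.1, 0.9], [1, 1])


class TestPepScores:
    def _expr(self, cols, genes):
        vals = np.column_stack(cols).astype(float)
        return fa.ExpressionMatrix([f"n{i}" for i in range(vals.shape[0])],
                                   genes, vals)

    def test_identical_to_reference_scores_one(self):
        ref = [0, 1, 2, 3, 4, 5]
        expr = self._expr([ref, ref], ["R1", "TWIN"])
        pep = V.pep_scores(expr, fa.GeneSet(["R1"]))
        assert pep["TWIN"] == pytest.approx(1.0)

    def test_inverse_pattern_scores_minus_one(self):
        expr = self._expr([[0, 0, 1, 1], [1, 1, 0, 0]], ["R1", "ANTI"])
        pep = V.pep_scores(expr, fa.GeneSet(["R1"]))
        assert pep["ANTI"] == pytest.approx(-1.0)

    def test_self_correlation_excluded(self):
        expr = self._expr([[0, 1, 2, 3], [3, 1, 2, 0]], ["R1", "R2"])
        pep = V.pep_scores(expr, fa.GeneSet(["R1", "R2"]))
        # R1's only partner is R2, never itself
        rho = stats.spearmanr([0, 1, 2, 3], [3, 1, 2, 0]).statistic
        assert pep["R1"] == pytest.approx(rho)

    def test_max_over_references_via_rank_oracle(self):
        rng = np.random.default_rng(3)
        g = rng.gamma(1.0, size=6)
        r1, r2 = rng.gamma(1.0, size=6), rng.gamma(1.0, size=6)
        expr = self._expr([r1, r2, g], ["R1", "R2", "G"])
        pep = V.pep_scores(expr, fa.GeneSet(["R1", "R2"]))
        oracle = max(stats.spearmanr(g, r1).statistic,
                     stats.spearmanr(g, r2).statistic)
        assert pep["G"] == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        g = rng.gamma(1.0, size=20)
        r = rng.gamma(1.0, size=20)
        a = V.pep_scores(self._expr([r, g], ["R", "G"]), fa.GeneSet(["R"]))
        b = V.pep_scores(self._expr([r, np.expm1(2 * g)], ["R", "G"]),
                         fa.GeneSet(["R"]))
        assert a["G"] == pytest.approx(b["G"], abs=1e-12)

    def test_constant_gene_is_nan(self):
        expr = self._expr([[0, 1, 2, 3], [5, 5, 5, 5]], ["R1", "CONST"])
        pep = V.pep_scores(expr, fa.GeneSet(["R1"]))
        assert math.isnan(pep["CONST"])


class TestPepThreshold:
    def _inputs(self, peps, aucs):
        genes = [f"R{i}" for i in range(len(peps))]
        pep = V.PEPTable(dict(zip(genes, peps)), fa.GeneSet(genes), 10)
        rep = V.ValidationReport(dict(zip(genes, aucs)), ())
        return pep, rep

    def test_all_perfect_returns_min_pep(self):
        pep, rep = self._inputs([0.4, 0.1, 0.7, 0.3], [1.0] * 4)
        assert V.pep_threshold(pep, rep) == pytest.approx(0.1)

    def test_no_crossing_falls_back_to_default(self):
        pep, rep = self._inputs([0.1, 0.2, 0.3, 0.4], [0.5] * 4)
        with pytest.warns(V.ValidationWarning):
            assert V.pep_threshold(pep, rep) == pytest.approx(0.13)

    def test_persistent_crossing(self):
        # low-PEP genes at chance, high-PEP genes informative
        peps = [0.05, 0.1, 0.2, 0.3, 0.5, 0.6]
        aucs = [0.4, 0.45, 0.8, 0.9, 0.95, 1.0]
        pep, rep = self._inputs(peps, aucs)
        thr = V.pep_threshold(pep, rep, bins=3)
        assert thr == pytest.approx(0.2)  # first bin whose mean stays > 0.5

    def test_too_few_genes(self):
        pep, rep = self._inputs([0.1, 0.2], [1.0, 1.0])
        with pytest.raises(ValueError):
            V.pep_threshold(pep, rep, allow_default=False)


class TestLoocv:
    def test_strong_signal_recovers_patterns(self, synth):
        assert synth["loocv"].average >= 0.8

    def test_exclusion_list_changes_average_only(self, synth):
        rep = synth["loocv"]
        worst = min(rep.per_gene, key=rep.per_gene.get)
        excluded = V.ValidationReport(rep.per_gene, (worst,))
        included = [v for g, v in rep.per_gene.items() if g != worst]
        assert excluded.average == pytest.approx(float(np.mean(included)))
        assert worst in excluded.per_gene  # still reported per gene


class TestSequentialElimination:
    def test_step_zero_reproduces_loocv(self, synth):
        res = synth["result"]
        traj = V.sequential_elimination(
            res.expr, res.spatial_map, fa.OTConfig(), fa.DistanceConfig(),
            order="desc", selected_genes=res.selected_genes,
            loocv=synth["loocv"], max_steps=1)
        assert traj[0]["per_gene"] == synth["loocv"].per_gene
        assert traj[0]["mean_auroc"] == pytest.approx(synth["loocv"].average)

    def test_desc_degrades_faster_than_asc(self, synth):
        """Removing the most inter-correlated reference genes first erodes
        held-out prediction of the removed genes faster than removing the
        least correlated first (full elimination trajectories)."""
        res = synth["result"]
        kw = dict(selected_genes=res.selected_genes, loocv=synth["loocv"])
        desc = V.sequential_elimination(res.expr, res.spatial_map,
                                        fa.OTConfig(), fa.DistanceConfig(),
                                        order="desc", **kw)
        asc = V.sequential_elimination(res.expr, res.spatial_map,
                                       fa.OTConfig(), fa.DistanceConfig(),
                                       order="asc", **kw)
        drop_desc = desc[1]["mean_auroc"] - desc[-1]["mean_auroc"]
        drop_asc = asc[1]["mean_auroc"] - asc[-1]["mean_auroc"]
        assert drop_desc > drop_asc


class TestPseudobulk:
    def test_self_correlation_is_one(self, toy_expr):
        pooled = toy_expr.values.sum(axis=0)
        bulk = dict(zip(toy_expr.genes, pooled))
        assert V.pseudobulk_correlation(toy_expr, bulk) == pytest.approx(1.0)

    def test_log_anticollinear_bulk(self, toy_expr):
        pooled = toy_expr.values.sum(axis=0)
        # construct bulk anti-collinear with the pooled vector in log space
        bulk_v = np.exp2(10.0 - np.log2(pooled + 1)) - 1
        bulk = dict(zip(toy_expr.genes, bulk_v))
        assert V.pseudobulk_correlation(toy_expr, bulk) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        vals = np.array([[1.0, 3.0, 0.0, 7.0]])
        expr = fa.ExpressionMatrix(["n0"], ["a", "b", "c", "d"], vals)
        bulk = {"a": 3.0, "b": 1.0, "c": 0.0, "d": 15.0}
        x = np.log2(vals[0] + 1)
        y = np.log2(np.array([3.0, 1.0, 0.0, 15.0]) + 1)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert V.pseudobulk_correlation(expr, bulk) == pytest.approx(expected)

    def test_too_few_shared_genes(self, toy_expr):
        with pytest.raises(ValueError):
            V.pseudobulk_correlation(toy_expr, {"G1": 1.0, "G2": 2.0})


def test_pep_auroc_positive_association(synth):
    """Reliable genes (high PEP) are the well-predicted ones: Spearman
    association between per-probe PEP and per-probe AUROC exceeds 0.5."""
    res, truth = synth["result"], synth["truth"]
    pep = V.pep_scores(res.expr,
                       fa.GeneSet([str(g) for g in res.spatial_map.ref_genes]))
    cell_pos = {str(c): i for i, c in enumerate(truth.cell_ids)}
    rows = np.array([cell_pos[str(c)] for c in res.spatial_map.cell_ids])
    peps, aucs = [], []
    for j, g in enumerate(map(str, truth.probe_genes)):
        prof = truth.probe_profiles[rows, j]
        if len(np.unique(prof)) < 2:
            continue
        labels = (prof > (prof.min() + prof.max()) / 2).astype(int)
        if labels.min() == labels.max():
            continue
        peps.append(pep[g])
        aucs.append(V.auroc(res.atlas.gene_values(g), labels))
    assert len(peps) >= 30
    rho = stats.spearmanr(peps, aucs).statistic
    assert rho > 0.5
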