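"""Domain gene selection, clustering, and per-domain quantification."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import floratlas as fa
from floratlas import domains as D
from floratlas.otmap import ReconstructedAtlas
from floratlas.validate import PEPTable


def _atlas(values, genes=None, ids=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    return ReconstructedAtlas(np.asarray(ids, dtype=object),
                              np.asarray(genes, dtype=object), values)


def _pep(genes, scores):
    return PEPTable(dict(zip(genes, scores)), fa.GeneSet([]), 0)


class TestSelectDomainGenes:
    def test_joint_predicates(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=100)
        vals = np.column_stack([
            base * np.sqrt(1.0), base * np.sqrt(4.0), base * np.sqrt(10.0)
        ])
        vals -= vals.min()
        atlas = _atlas(vals, ["a", "b", "c"])
        var = atlas.values.var(axis=0)
        pep = _pep(["a", "b", "c"], [0.9, 0.05, 0.9])
        sel = D.select_domain_genes(atlas, pep, pep_min=0.13,
                                    var_min=float(np.sort(var)[1]))
        assert list(sel) == ["c"]  # b fails PEP, a fails variance

    def test_boundary_is_strict(self):
        atlas = _atlas(np.column_stack([np.linspace(0, 10, 50)]), ["a"])
        pep = _pep(["a"], [0.13])
        with pytest.raises(ValueError):
            D.select_domain_genes(atlas, pep, pep_min=0.13, var_min=0.0)

    def test_constant_gene_never_selected(self):
        atlas = _atlas(np.ones((10, 1)), ["a"])
        with pytest.raises(ValueError):
            D.select_domain_genes(atlas, _pep(["a"], [0.99]), var_min=0.0)


class TestStandardizeLog:
    def test_hand_computed(self):
        atlas = _atlas([[0.0], [1.0], [3.0]], ["a"])
        out = D.standardize_log(atlas, fa.GeneSet(["a"]))
        np.testing.assert_allclose(out[:, 0], [-1.22474487, 0.0, 1.22474487])

    def test_constant_gene_maps_to_zero(self):
        atlas = _atlas(np.full((5, 1), 2.0), ["a"])
        out = D.standardize_log(atlas, fa.GeneSet(["a"]))
        np.testing.assert_array_equal(out[:, 0], np.zeros(5))

    def test_output_moments(self):
        rng = np.random.default_rng(2)
        atlas = _atlas(rng.gamma(2.0, size=(40, 3)))
        out = D.standardize_log(atlas, fa.GeneSet(list(atlas.genes)))
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.var(axis=0), 1, atol=1e-12)


class TestClusterDomains:
    def test_degenerate_cuts(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 2))
        assert len(set(D.cluster_domains(X, k=1).labels)) == 1
        assert len(set(D.cluster_domains(X, k=8).labels)) == 8
        with pytest.raises(ValueError):
            D.cluster_domains(X, k=9)

    def test_two_separated_blobs(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.1, size=(20, 3)),
                       rng.normal(50, 0.1, size=(12, 3))])
        asg = D.cluster_domains(X, k=2)
        membership = np.array([0] * 20 + [1] * 12)
        assert adjusted_rand_score(membership, asg.labels) == 1.0
        # labels ordered by decreasing size: big blob is domain 1
        assert (asg.labels[:20] == 1).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 4))
        perm = rng.permutation(30)
        a = D.cluster_domains(X, k=5).labels
        b = D.cluster_domains(X[perm], k=5).labels
        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_painted_domains_recovered_under_default_noise(self):
        """Cells painted with 4 archetype expression programs + default
        lognormal noise are recovered at the true k with ARI >= 0.9."""
        rng = np.random.default_rng(1)
        k, n, g = 4, 300, 12
        labels = rng.integers(k, size=n)
        programs = rng.uniform(0.5, 4.0, size=(k, g)) * rng.integers(
            0, 2, size=(k, g))
        values = programs[labels] * rng.lognormal(0.0, 0.3, size=(n, g))
        atlas = _atlas(fa.log_normalize(values))
        std = D.standardize_log(atlas, fa.GeneSet(list(atlas.genes)))
        asg = D.cluster_domains(std, k=k)
        assert adjusted_rand_score(labels, asg.labels) >= 0.9


class TestDomainMeans:
    def test_direct_arithmetic(self):
        atlas = _atlas([[1.0], [3.0], [5.0]], ["a"])
        asg = D.DomainAssignment([1, 1, 2], 2, fa.GeneSet(["a"]))
        table = D.domain_means(atlas, asg)
        np.testing.assert_allclose(table.means[:, 0], [2.0, 5.0])
        assert table.counts.tolist() == [2, 1]
        assert table.counts.sum() == 3

    def test_constant_gene(self):
        atlas = _atlas(np.full((4, 1), 7.0), ["a"])
        asg = D.DomainAssignment([1, 2, 1, 2], 2, fa.GeneSet(["a"]))
        np.testing.assert_allclose(D.domain_means(atlas, asg).means, 7.0)

    def test_refinement_conserves_global_mean(self):
        rng = np.random.default_rng(6)
        atlas = _atlas(rng.random((20, 3)))
        asg = D.DomainAssignment(rng.integers(1, 5, size=20), 4,
                                 fa.GeneSet([]))
        table = D.domain_means(atlas, asg)
        weighted = (table.means * table.counts[:, None]).sum(axis=0) \
            / table.counts.sum()
        np.testing.assert_allclose(weighted, atlas.values.mean(axis=0))

    def test_empty_domain_warns_nan(self):
        atlas = _atlas([[1.0], [2.0]], ["a"])
        asg = D.DomainAssignment([1, 1], 2, fa.GeneSet(["a"]))
        with pytest.warns(UserWarning):
            table = D.domain_means(atlas, asg)
        assert np.isnan(table.means[1, 0])


class TestHomeoticDomains:
    def test_whorl_mean_and_fold_change(self, toy_map):
        atlas = _atlas(np.arange(6, dtype=float)[:, None], ["a"],
                       list(toy_map.cell_ids))
        # G1-positive cells: 0,1,2,5 ; G2-positive: 2,3,4,5
        m1 = D.homeotic_domain_expression(atlas, toy_map, "G1")
        m2 = D.homeotic_domain_expression(atlas, toy_map, "G2")
        assert m1["a"] == pytest.approx(2.0)
        assert m2["a"] == pytest.approx(3.5)
        both = D.homeotic_domain_expression(atlas, toy_map, ("G1", "G2"))
        assert both["a"] == pytest.approx(3.5)  # cells 2 and 5
        lfc = D.domain_log2_fold_change({"a": 3.0}, {"a": 1.0})
        assert lfc["a"] == pytest.approx(1.0)

    def test_all_cells_domain_equals_global_mean(self, toy_map):
        atlas = _atlas(np.arange(6, dtype=float)[:, None], ["a"],
                       list(toy_map.cell_ids))
        m = fa.SpatialMap(toy_map.cell_ids, toy_map.coords, ["ALL"],
                          np.ones((6, 1), dtype=int))
        out = D.homeotic_domain_expression(atlas, m, "ALL")
        assert out["a"] == pytest.approx(atlas.values.mean())


class TestTemporalFoldChange:
    def _table(self, means):
        means = np.asarray(means, dtype=float)
        return D.DomainExpressionTable(
            np.arange(1, means.shape[0] + 1),
            np.asarray([f"g{j}" for j in range(means.shape[1])], dtype=object),
            means, np.ones(means.shape[0], dtype=int))

    def test_identity_gives_empty_lists(self):
        t = self._table([[1.0, 2.0], [3.0, 4.0]])
        out = D.temporal_fold_change(t, t)
        assert all(v == {"up": [], "down": []} for v in out.values())

    def test_strict_boundary_and_inclusion(self):
        a = self._table([[3.0, 7.0]])
        b = self._table([[1.0, 1.0]])
        out = D.temporal_fold_change(a, b, lfc_min=1.0)
        # (3+1)/(1+1) -> exactly 1, excluded; (7+1)/(1+1) -> 2, included
        assert out[1]["up"] == ["g1"]

    def test_label_mismatch_rejected(self):
        a = self._table([[1.0]])
        b = D.DomainExpressionTable(np.array([2]), a.genes, a.means, a.counts)
        with pytest.raises(ValueError):
            D.temporal_fold_change(a, b)


class TestSignatureAndRelative:
    def test_self_subtraction_is_zero(self):
        table = {f"g{i}": np.array([float(i), 2.0 * i]) for i in range(5)}
        genes = fa.GeneSet(list(table))
        out = D.signature_relative_expression(genes, table, genes)
        np.testing.assert_allclose(out["relative_median"], 0.0)

    def test_median_difference(self):
        table = {"a": np.array([5.0]), "b": np.array([5.0]),
                 "x": np.array([3.0]), "y": np.array([3.0]),
                 "z": np.array([3.0])}
        out = D.signature_relative_expression(
            fa.GeneSet(["a", "b"]), table, fa.GeneSet(["x", "y", "z"]))
        assert out["relative_median"][0] == pytest.approx(2.0)

    def test_relative_expression_centering(self):
        out = D.relative_expression(np.array([[2.0, 4.0, 6.0],
                                              [5.0, 5.0, 5.0]]))
        np.testing.assert_allclose(out[0], [-2.0, 0.0, 2.0])
        np.testing.assert_allclose(out[1], 0.0)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
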