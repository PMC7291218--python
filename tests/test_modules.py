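"""Module detection: clustering, cutting, eigengenes, merging, filtering."""

import numpy as np
import pytest

from braincoex.expression_io import ValidationError
from braincoex.modules import (
    BACKGROUND,
    ModuleAssignment,
    cut_modules,
    filter_modules,
    hierarchical_cluster,
    merge_close_modules,
    module_coherence,
    module_eigengene,
    module_eigengenes,
    module_membership,
)
from braincoex.network import TOMMatrix
from braincoex.simulate import generate_expression
from conftest import make_expression


def block_tom(sizes, within=0.9, between=0.05, seed=None):
    """TOM with planted diagonal blocks (optionally jittered)."""
    n = sum(sizes)
    values = np.full((n, n), between)
    start = 0
    for size in sizes:
        values[start:start + size, start:start + size] = within
        start += size
    if seed is not None:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-0.02, 0.02, (n, n))
        values = np.clip(values + (jitter + jitter.T) / 2, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return TOMMatrix(
        gene_ids=np.array([f"G{i}" for i in range(n)], dtype=object), values=values
    )


class TestHierarchicalCluster:
    def test_two_blocks_are_top_split(self):
        tom = block_tom([5, 5], within=1.0, between=0.0)
        dendro = hierarchical_cluster(tom)
        # the final (highest) merge joins the two blocks
        heights = dendro.linkage_matrix[:, 2]
        assert heights[-1] == pytest.approx(1.0)
        assert np.all(heights[:-1] <= 1e-12)

    def test_merge_heights_nondecreasing(self, rng):
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        tom = TOMMatrix(
            gene_ids=np.array([f"G{i}" for i in range(8)], dtype=object), values=a
        )
        heights = hierarchical_cluster(tom).linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_nonfinite_rejected(self):
        tom = block_tom([3, 3])
        tom.values[0, 1] = np.nan
        with pytest.raises(ValidationError, match="non-finite"):
            hierarchical_cluster(tom)


class TestCutModules:
    def test_planted_partition_recovered(self):
        tom = block_tom([12, 11, 10], seed=0)
        assignment = cut_modules(hierarchical_cluster(tom), min_module_size=5)
        assert sorted(assignment.module_sizes.values(), reverse=True) == [12, 11, 10]
        # labels ordered by decreasing size
        assert assignment.module_sizes[1] == 12

    def test_small_clusters_become_background(self):
        tom = block_tom([25, 25, 5], within=0.95, between=0.02, seed=1)
        assignment = cut_modules(hierarchical_cluster(tom), min_module_size=20)
        assert len(assignment.module_labels) == 2
        assert int((assignment.labels == BACKGROUND).sum()) == 5

    def test_oversized_threshold_warns(self):
        tom = block_tom([5, 5])
        with pytest.warns(UserWarning, match="minimum size"):
            assignment = cut_modules(hierarchical_cluster(tom), min_module_size=100)
        assert not assignment.module_labels


class TestModuleEigengene:
    def test_rank_one_module(self, rng):
        profile = rng.standard_normal(30)
        # genes are affine copies of one profile -> identical after standardization
        expr = make_expression(
            np.vstack([2.0 * profile + 1.0, profile, -3.0 * profile + 0.5])
        )
        me = module_eigengene(expr, expr.gene_ids)
        assert me.variance_explained == pytest.approx(1.0, abs=1e-10)
        std = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(
            np.abs(me.values), np.abs(std) / np.linalg.norm(std), atol=1e-10
        )

    def test_antisymmetric_pair_is_rank_one(self, rng):
        profile = rng.standard_normal(25)
        expr = make_expression(np.vstack([profile, -profile]))
        me = module_eigengene(expr, expr.gene_ids)
        assert me.variance_explained == pytest.approx(1.0, abs=1e-10)

    def test_recovers_latent_factor(self):
        expr, truth = generate_expression(1, 20, 0, 100, 0.8, seed=5)
        me = module_eigengene(expr, truth.module_genes(1))
        r = np.corrcoef(me.values, truth.factor_profiles[0])[0, 1]
        assert abs(r) >= 0.95

    def test_sign_convention_positive_with_mean(self, rng):
        for _ in range(20):
            expr = make_expression(rng.standard_normal((6, 15)))
            me = module_eigengene(expr, expr.gene_ids)
            X = expr.values
            Xs = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            mean_profile = Xs.mean(0)
            assert np.corrcoef(me.values, mean_profile)[0, 1] >= 0

    def test_gene_order_invariance_up_to_sign(self, rng):
        expr = make_expression(rng.standard_normal((8, 20)))
        me1 = module_eigengene(expr, list(expr.gene_ids))
        me2 = module_eigengene(expr, list(expr.gene_ids[::-1]))
        np.testing.assert_allclose(me1.values, me2.values, atol=1e-10)

    def test_too_few_genes(self, small_expr):
        with pytest.raises(ValidationError):
            module_eigengene(small_expr, ["G0"])

    def test_zero_variance_gene(self, rng):
        values = rng.standard_normal((3, 10))
        values[2] = 1.0
        with pytest.raises(ValidationError, match="zero-variance"):
            module_eigengene(make_expression(values), ["G0", "G1", "G2"])


class TestMergeCloseModules:
    def test_same_factor_modules_merge(self):
        # two "modules" driven by one latent factor
        expr, truth = generate_expression(1, 40, 0, 100, 0.85, seed=2)
        labels = np.array([1] * 20 + [2] * 20)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        merged = merge_close_modules(expr, assignment, merge_height=0.15)
        assert len(merged.module_labels) == 1

    def test_zero_height_is_identity(self):
        expr, _ = generate_expression(2, 20, 0, 50, 0.8, seed=3)
        labels = np.array([1] * 20 + [2] * 20)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        merged = merge_close_modules(expr, assignment, merge_height=0.0)
        np.testing.assert_array_equal(merged.labels, assignment.labels)

    def test_orthogonal_factors_unchanged(self):
        expr, _ = generate_expression(3, 30, 0, 200, 0.9, seed=4)
        labels = np.repeat([1, 2, 3], 30)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        merged = merge_close_modules(expr, assignment, merge_height=0.15)
        assert len(merged.module_labels) == 3

    def test_postcondition_all_dissimilar(self):
        expr, _ = generate_expression(4, 25, 0, 60, 0.8, seed=6)
        labels = np.repeat([1, 2, 3, 4], 25)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        merged = merge_close_modules(expr, assignment, merge_height=0.3)
        mes = module_eigengenes(expr, merged)
        labs = sorted(mes)
        for i, la in enumerate(labs):
            for lb in labs[i + 1:]:
                r = np.corrcoef(mes[la].values, mes[lb].values)[0, 1]
                assert 1.0 - r >= 0.3 - 1e-9


class TestFilterModules:
    def test_small_module_removed_regardless_of_coherence(self):
        expr, truth = generate_expression(1, 8, 0, 50, 0.99, seed=7)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=np.ones(8, int))
        filtered = filter_modules(expr, assignment, min_genes=10)
        assert not filtered.module_labels

    def test_coherent_module_retained(self, rng):
        profile = rng.standard_normal(40)
        expr = make_expression(
            np.vstack([profile * s for s in rng.uniform(0.5, 2.0, 12)])
        )
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=np.ones(12, int))
        filtered = filter_modules(expr, assignment)
        assert filtered.module_labels == [1]

    def test_incoherent_module_removed(self):
        # kME target 0.6 -> mean membership well below the 0.75 bar
        expr, _ = generate_expression(1, 30, 0, 300, 0.6, seed=8)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=np.ones(30, int))
        assert module_coherence(expr, expr.gene_ids) < 0.75
        filtered = filter_modules(expr, assignment, min_cor=0.75)
        assert not filtered.module_labels

    def test_idempotent(self):
        expr, _ = generate_expression(3, 30, 10, 80, 0.85, seed=9)
        labels = np.concatenate([np.repeat([1, 2, 3], 30), np.zeros(10, int)])
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        once = filter_modules(expr, assignment)
        twice = filter_modules(expr, once)
        np.testing.assert_array_equal(once.labels, twice.labels)

    def test_pairwise_mode(self, rng):
        profile = rng.standard_normal(40)
        expr = make_expression(np.vstack([profile + 0.01 * rng.standard_normal(40)
                                          for _ in range(12)]))
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=np.ones(12, int))
        filtered = filter_modules(expr, assignment, mode="pairwise")
        assert filtered.module_labels == [1]


class TestModuleMembership:
    def test_gene_equal_to_eigengene(self):
        expr, truth = generate_expression(1, 10, 0, 40, 0.9, seed=10)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=np.ones(10, int))
        mes = module_eigengenes(expr, assignment)
        # append the eigengene itself as a gene
        values = np.vstack([expr.values, mes[1].values])
        expr2 = make_expression(values,
                                gene_ids=list(expr.gene_ids) + ["ME_COPY"],
                                sample_ids=list(expr.sample_ids))
        kme, labels = module_membership(expr2, mes)
        assert kme[-1, 0] == pytest.approx(1.0, abs=1e-10)

    def test_orthogonal_gene_has_zero_membership(self, rng):
        n = 40
        profile = rng.standard_normal(n)
        ortho = rng.standard_normal(n)
        profile -= profile.mean()
        ortho -= ortho.mean()
        ortho -= (ortho @ profile) / (profile @ profile) * profile
        expr = make_expression(np.vstack([profile, 1.5 * profile, ortho]))
        assignment = ModuleAssignment(
            gene_ids=expr.gene_ids, labels=np.array([1, 1, 0])
        )
        mes = module_eigengenes(expr, assignment)
        kme, _ = module_membership(expr, mes)
        assert kme[2, 0] == pytest.approx(0.0, abs=1e-10)

    def test_own_module_membership_dominates(self):
        expr, truth = generate_expression(3, 30, 0, 100, 0.8, seed=11)
        labels = truth.labels_for(expr.gene_ids)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=labels)
        mes = module_eigengenes(expr, assignment)
        kme, mod_labels = module_membership(expr, mes)
        for j, lab in enumerate(mod_labels):
            own = kme[labels == lab, j].mean()
            other = kme[labels != lab, j].mean()
            assert own > other

    def test_sample_mismatch_rejected(self):
        expr, _ = generate_expression(1, 10, 0, 40, 0.9, seed=12)
        assignment = ModuleAssignment(gene_ids=expr.gene_ids, labels=np.ones(10, int))
        mes = module_eigengenes(expr, assignment)
        other = make_expression(expr.values[:, :20],
                                gene_ids=list(expr.gene_ids))
        with pytest.raises(ValidationError, match="samples"):
            module_membership(other, mes)
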