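"""AHP core: matrix validation, sum-product weights, consistency, hierarchy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stabeval import (
    CR_THRESHOLD,
    RANDOM_CONSISTENCY_INDEX,
    HierarchyNode,
    JudgmentMatrix,
    JudgmentMatrixError,
    WeightVector,
    aggregate_experts,
    column_normalize,
    compose_weights,
    consistency,
    lambda_max,
    make_consistent_matrix,
    priority_vector,
    validate_judgment_matrix,
)

from conftest import eigen_lambda_max, eigen_priority


def reciprocal(upper):
    """Build a reciprocal matrix from its strict upper triangle."""
    n = int((1 + np.sqrt(1 + 8 * len(upper))) / 2)
    m = np.ones((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = upper[k]
            m[j, i] = 1 / upper[k]
            k += 1
    return m


class TestValidation:
    def test_all_ones_matrix_is_valid(self):
        m = validate_judgment_matrix(np.ones((3, 3)))
        assert m.n == 3

    def test_reciprocal_construction_is_valid(self):
        m = reciprocal([3, 5, 2])  # b12=3, b13=5, b23=2
        validate_judgment_matrix(m, strict=True)

    def test_reciprocity_violation_names_cell(self):
        m = np.array([[1, 3], [0.5, 1]])
        with pytest.raises(JudgmentMatrixError, match=r"\(2,1\)"):
            validate_judgment_matrix(m)

    def test_non_square_rejected(self):
        with pytest.raises(JudgmentMatrixError, match="square"):
            validate_judgment_matrix(np.ones((2, 3)))

    def test_non_positive_entry_rejected(self):
        m = reciprocal([3, 5, 2])
        m[0, 1] = 0.0
        with pytest.raises(JudgmentMatrixError, match="positive"):
            validate_judgment_matrix(m)

    def test_bad_diagonal_rejected(self):
        m = np.ones((3, 3))
        m[1, 1] = 2.0
        with pytest.raises(JudgmentMatrixError, match="diagonal"):
            validate_judgment_matrix(m)

    def test_strict_rejects_off_scale_entry(self):
        m = reciprocal([2.5, 3, 2])
        validate_judgment_matrix(m)  # fine without strict
        with pytest.raises(JudgmentMatrixError, match="Saaty"):
            validate_judgment_matrix(m, strict=True)


class TestSumProduct:
    def test_column_normalize_all_ones(self):
        out = column_normalize(JudgmentMatrix(np.ones((3, 3))))
        assert np.allclose(out, 1 / 3)

    def test_column_normalize_2x2(self):
        out = column_normalize(JudgmentMatrix(np.array([[1, 3], [1 / 3, 1]])))
        assert np.allclose(out[:, 0], [0.75, 0.25])
        assert np.allclose(out[:, 1], [0.75, 0.25])

    def test_columns_sum_to_one_any_matrix(self):
        m = make_consistent_matrix([0.4, 0.3, 0.2, 0.1], noise=0.3, seed=7)
        assert np.allclose(column_normalize(m).sum(axis=0), 1.0)

    def test_uniform_matrix_gives_uniform_weights(self):
        w = priority_vector(JudgmentMatrix(np.ones((3, 3))))
        assert np.allclose(w.weights, 1 / 3)

    def test_consistent_matrix_recovers_weights_exactly(self):
        truth = np.array([0.6, 0.3, 0.1])
        m = JudgmentMatrix(np.outer(truth, 1 / truth))
        assert np.allclose(priority_vector(m).weights, truth, atol=1e-9)

    def test_matches_eigenvector_oracle_on_noisy_matrix(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = make_consistent_matrix(
                rng.dirichlet(np.ones(5)) + 0.02, noise=0.2, seed=rng
            )
            assert np.max(
                np.abs(priority_vector(m).weights - eigen_priority(m.entries))
            ) < 0.02

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        w0 = rng.dirichlet(np.ones(n)) + 0.05
        m = make_consistent_matrix(w0 / w0.sum(), noise=0.4, seed=rng)
        perm = rng.permutation(n)
        mp = JudgmentMatrix(m.entries[np.ix_(perm, perm)])
        assert np.allclose(
            priority_vector(mp).weights, priority_vector(m).weights[perm]
        )

    def test_weights_sum_to_one(self):
        m = make_consistent_matrix([0.5, 0.3, 0.2], noise=0.5, seed=11)
        assert abs(priority_vector(m).weights.sum() - 1.0) < 1e-12


class TestLambdaMaxAndConsistency:
    def test_uniform_matrix_lambda_is_n(self):
        m = JudgmentMatrix(np.ones((3, 3)))
        assert lambda_max(m, priority_vector(m)) == pytest.approx(3.0)

    def test_consistent_matrix_lambda_is_n(self):
        truth = np.array([0.6, 0.3, 0.1])
        m = JudgmentMatrix(np.outer(truth, 1 / truth))
        assert lambda_max(m) == pytest.approx(3.0, abs=1e-9)

    def test_lambda_matches_eigen_oracle(self):
        # b12=1, b13=3, b23=1
        m = JudgmentMatrix(reciprocal([1, 3, 1]))
        assert lambda_max(m) == pytest.approx(eigen_lambda_max(m.entries), abs=1e-3)

    def test_zero_weight_raises_named_division_error(self):
        m = JudgmentMatrix(np.ones((2, 2)))
        with pytest.raises(ZeroDivisionError, match="component 1"):
            lambda_max(m, WeightVector(np.array([0.0, 1.0])))

    def test_consistent_matrix_passes_with_zero_cr(self):
        truth = np.array([0.5, 0.25, 0.15, 0.1])
        rep = consistency(JudgmentMatrix(np.outer(truth, 1 / truth)))
        assert rep.ci == pytest.approx(0.0, abs=1e-9)
        assert rep.cr == pytest.approx(0.0, abs=1e-9)
        assert rep.passed

    def test_ri_lookup_order_3(self):
        rep = consistency(JudgmentMatrix(np.ones((3, 3))))
        assert rep.ri == 0.58

    @pytest.mark.parametrize("n,ri", sorted(RANDOM_CONSISTENCY_INDEX.items()))
    def test_ri_table(self, n, ri):
        rep = consistency(JudgmentMatrix(np.ones((n, n))))
        assert rep.ri == ri

    def test_maximally_contradictory_matrix_fails(self):
        # a 3-cycle: 1 >> 2 >> 3 >> 1
        m = JudgmentMatrix(reciprocal([9, 1 / 9, 9]))
        rep = consistency(m)
        # oracle: CR from the true principal eigenvalue
        cr_oracle = ((eigen_lambda_max(m.entries) - 3) / 2) / 0.58
        assert cr_oracle > CR_THRESHOLD
        assert not rep.passed
        assert rep.cr == pytest.approx(cr_oracle, rel=1e-6)

    def test_order_2_defines_cr_zero(self):
        rep = consistency(JudgmentMatrix(np.array([[1, 7], [1 / 7, 1]])))
        assert rep.cr == 0.0 and rep.passed

    def test_order_above_9_unsupported(self):
        with pytest.raises(ValueError, match="1..9"):
            consistency(JudgmentMatrix(np.ones((10, 10))))

    def test_lambda_at_least_n_on_perturbed_matrices(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            w0 = rng.dirichlet(np.ones(n)) + 0.02
            m = make_consistent_matrix(w0 / w0.sum(), noise=0.5, seed=rng)
            rep = consistency(m)
            assert rep.lambda_max >= n - 1e-9
            assert rep.ci > 0  # noise breaks exact consistency


class TestAggregation:
    def test_single_expert_passthrough(self):
        v = WeightVector(np.array([0.7, 0.3]))
        agg, excluded = aggregate_experts([v])
        assert np.allclose(agg.weights, v.weights)
        assert excluded == []

    def test_two_expert_mean(self):
        a = WeightVector(np.array([0.6, 0.4]))
        b = WeightVector(np.array([0.4, 0.6]))
        agg, _ = aggregate_experts([a, b])
        assert np.allclose(agg.weights, [0.5, 0.5])

    def test_inconsistent_expert_excluded(self):
        good = make_consistent_matrix([0.6, 0.3, 0.1], saaty_round=True)
        bad = JudgmentMatrix(reciprocal([9, 1 / 9, 9]))
        agg, excluded = aggregate_experts([good, bad])
        assert excluded == [1]
        assert np.allclose(agg.weights, priority_vector(good).weights)

    def test_all_excluded_raises(self):
        bad = JudgmentMatrix(reciprocal([9, 1 / 9, 9]))
        with pytest.raises(ValueError, match="no expert"):
            aggregate_experts([bad])

    def test_expert_weights_shift_mean(self):
        a = WeightVector(np.array([0.6, 0.4]))
        b = WeightVector(np.array([0.4, 0.6]))
        agg, _ = aggregate_experts([a, b], expert_weights=[3, 1])
        assert np.allclose(agg.weights, [0.55, 0.45])

    def test_geometric_matrix_aggregation_preserves_reciprocity(self):
        panel = [
            make_consistent_matrix([0.5, 0.3, 0.2], noise=0.1, seed=s)
            for s in range(4)
        ]
        agg, _ = aggregate_experts(panel, method="matrix_geometric")
        assert abs(agg.weights.sum() - 1.0) < 1e-12


class TestHierarchy:
    def test_single_level_weights_unchanged(self):
        root = HierarchyNode("A", 1.0, [
            HierarchyNode("x", 0.7), HierarchyNode("y", 0.3),
        ])
        assert compose_weights(root) == {"x": 0.7, "y": 0.3}

    def test_three_level_products(self):
        root = HierarchyNode("A", 1.0, [
            HierarchyNode("B1", 0.6, [
                HierarchyNode("C1", 0.5, [HierarchyNode("a", 0.4),
                                          HierarchyNode("b", 0.6)]),
                HierarchyNode("C2", 0.5, [HierarchyNode("c", 1.0)]),
            ]),
            HierarchyNode("B2", 0.4, [HierarchyNode("d", 1.0)]),
        ])
        w = compose_weights(root)
        assert w["a"] == pytest.approx(0.6 * 0.5 * 0.4)
        assert w["b"] == pytest.approx(0.6 * 0.5 * 0.6)
        assert w["c"] == pytest.approx(0.3)
        assert w["d"] == pytest.approx(0.4)
        assert sum(w.values()) == pytest.approx(1.0, abs=1e-6)

    def test_bad_sibling_sum_rejected(self):
        root = HierarchyNode("A", 1.0, [
            HierarchyNode("x", 0.7), HierarchyNode("y", 0.2),
        ])
        with pytest.raises(ValueError, match="sum"):
            compose_weights(root)

    def test_soil_branch_allocation(self):
        """The soil heavy-metal sub-branch carries 0.544 * 0.705 = 0.3835 of
        the total weight, split between available and total heavy metal."""
        from stabeval import load_hierarchy

        w = compose_weights(load_hierarchy())
        assert w["AHM"] + w["THM"] == pytest.approx(0.544 * 0.705, abs=1e-9)
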