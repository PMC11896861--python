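"""Fuzzy comprehensive evaluation: memberships, composition, defuzzification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from access5a.fce import (
    GRADE_LABELS,
    ResponseTable,
    compose,
    defuzzify,
    evaluate_hierarchy,
    membership_from_responses,
)

GRADES = (5.0, 4.0, 3.0, 2.0, 1.0)


class TestMembership:
    def test_unanimous_middle_grade(self):
        scores = pd.DataFrame({"A11": [3.0] * 10})
        membership = membership_from_responses(scores)
        assert membership.loc["A11"].tolist() == [0, 0, 1.0, 0, 0]

    def test_frequency_counts(self):
        # grades: 2 x V1(5), 3 x V2(4), 5 x V3(3)
        scores = pd.DataFrame({"A11": [5, 5, 4, 4, 4, 3, 3, 3, 3, 3]}, dtype=float)
        membership = membership_from_responses(scores)
        assert membership.loc["A11"].tolist() == pytest.approx([0.2, 0.3, 0.5, 0.0, 0.0])

    def test_identical_columns_identical_rows(self):
        col = [5, 4, 3, 3, 2]
        scores = pd.DataFrame({"A11": col, "A12": col}, dtype=float)
        membership = membership_from_responses(scores)
        assert membership.loc["A11"].tolist() == membership.loc["A12"].tolist()

    def test_rows_sum_to_one(self, small_responses):
        membership = membership_from_responses(small_responses)
        np.testing.assert_allclose(membership.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            membership_from_responses(pd.DataFrame({"A11": []}))

    def test_label_cells_parsed(self):
        frame = pd.DataFrame({"A11": ["V1", "V3", "V5", "V3"]})
        table = ResponseTable.from_frame(frame, ["A11"])
        membership = membership_from_responses(table)
        assert membership.loc["A11"].tolist() == pytest.approx([0.25, 0, 0.5, 0, 0.25])


class TestCompose:
    def test_single_item_identity(self):
        row = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        np.testing.assert_allclose(compose([0.37], row), row)

    def test_equal_weight_symmetry(self):
        rows = np.array([[1, 0, 0, 0, 0], [0, 0, 0, 0, 1]], dtype=float)
        np.testing.assert_allclose(compose([1, 1], rows), [0.5, 0, 0, 0, 0.5])

    def test_matches_bruteforce_weighted_sum(self):
        rng = np.random.default_rng(23)
        rows = rng.dirichlet(np.ones(5), size=4)
        weights = rng.uniform(0.1, 2.0, size=4)
        expected = np.zeros(5)
        renorm = weights / weights.sum()
        for r in range(4):
            for g in range(5):
                expected[g] += renorm[r] * rows[r, g]
        np.testing.assert_allclose(compose(weights, rows), expected, atol=1e-12)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compose([0.0, 0.0], np.ones((2, 5)) / 5)

    def test_max_min_operator_returns_unit_sum(self):
        rng = np.random.default_rng(8)
        rows = rng.dirichlet(np.ones(5), size=3)
        out = compose([0.5, 0.3, 0.2], rows, operator="max_min")
        assert out.sum() == pytest.approx(1.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 6))
    def test_weighted_average_conserves_membership(self, seed, k):
        rng = np.random.default_rng(seed)
        rows = rng.dirichlet(np.ones(5), size=k)
        weights = rng.uniform(0.01, 1.0, size=k)
        out = compose(weights, rows)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)
        assert (out >= -1e-12).all()


class TestDefuzzify:
    def test_published_worked_example(self):
        score = defuzzify((0.1241, 0.2989, 0.4005, 0.1390, 0.0374), GRADES)
        assert round(score, 4) == 3.3330

    @pytest.mark.parametrize(
        "vector, expected",
        [((1, 0, 0, 0, 0), 5.0), ((0.2, 0.2, 0.2, 0.2, 0.2), 3.0), ((0, 0, 0, 0, 1), 1.0)],
    )
    def test_degenerate_and_uniform_vectors(self, vector, expected):
        assert defuzzify(vector, GRADES) == pytest.approx(expected)

    def test_sum_tolerance_enforced(self):
        with pytest.raises(ValueError, match="deviates"):
            defuzzify((0.5, 0.1, 0.1, 0.1, 0.1), GRADES)

    def test_renormalize_option(self):
        vec = (0.1241, 0.2989, 0.4005, 0.1390, 0.0374)  # sums to 0.9999
        assert defuzzify(vec, GRADES, renormalize=True) == pytest.approx(3.3330 / 0.9999)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            defuzzify((-0.1, 0.4, 0.4, 0.2, 0.1), GRADES)


class TestEvaluateHierarchy:
    def test_unanimous_top_grade_fixed_point(self, small_hierarchy):
        scores = pd.DataFrame(
            {leaf: [5.0] * 8 for leaf in small_hierarchy.leaf_ids}
        )
        result = evaluate_hierarchy(scores, small_hierarchy)
        np.testing.assert_allclose(result.scores.to_numpy(), 5.0)

    def test_two_path_equivalence_with_flat_composition(self, small_hierarchy, small_responses):
        """Hierarchical composition equals a flat global-leaf-weight pass."""
        result = evaluate_hierarchy(small_responses, small_hierarchy)
        membership = membership_from_responses(small_responses)
        leaf_ids = small_hierarchy.leaf_ids
        global_weights = [small_hierarchy.node(l).weight for l in leaf_ids]
        flat = compose(global_weights, membership.loc[leaf_ids].to_numpy())
        np.testing.assert_allclose(
            result.memberships.loc["overall"].to_numpy(), flat, atol=1e-9
        )
        flat_score = defuzzify(flat, small_hierarchy.grade_values, tol=1e-6)
        assert result.overall_score == pytest.approx(flat_score, abs=1e-9)

    def test_parent_score_is_weighted_mean_of_children(self, small_hierarchy, small_responses):
        result = evaluate_hierarchy(small_responses, small_hierarchy)
        for level in (1, 2):
            for node in small_hierarchy.level_nodes(level):
                children = small_hierarchy.children(node.id)
                expected = sum(c.weight * result.scores[c.id] for c in children) / node.weight
                assert result.scores[node.id] == pytest.approx(expected, abs=1e-9)

    def test_membership_conservation_and_score_bounds(self, xian_hierarchy, small_responses):
        rng = np.random.default_rng(3)
        scores = pd.DataFrame(
            rng.integers(1, 6, size=(40, 37)).astype(float), columns=xian_hierarchy.leaf_ids
        )
        result = evaluate_hierarchy(scores, xian_hierarchy)
        np.testing.assert_allclose(result.memberships.sum(axis=1), 1.0, atol=1e-6)
        assert (result.scores >= 1.0 - 1e-9).all() and (result.scores <= 5.0 + 1e-9).all()

    def test_raising_one_response_never_lowers_ancestor_scores(self, small_hierarchy):
        rng = np.random.default_rng(19)
        base = pd.DataFrame(
            rng.integers(1, 5, size=(12, 4)).astype(float), columns=small_hierarchy.leaf_ids
        )
        before = evaluate_hierarchy(base, small_hierarchy).scores
        bumped = base.copy()
        bumped.iloc[0, 0] += 1.0
        after = evaluate_hierarchy(bumped, small_hierarchy).scores
        assert (after >= before - 1e-12).all()

    def test_missing_indicator_column_rejected(self, small_hierarchy):
        scores = pd.DataFrame({"A11": [3.0, 4.0]})
        with pytest.raises(ValueError, match="B11"):
            evaluate_hierarchy(scores, small_hierarchy)

    def test_table_layout_has_one_row_per_leaf(self, small_hierarchy, small_responses):
        result = evaluate_hierarchy(small_responses, small_hierarchy)
        table = result.to_table()
        assert len(table) == len(small_hierarchy.leaves)
        assert set(table.columns) >= {"primary_score", "secondary_score", "tertiary_score"}
        long = result.to_long()
        assert len(long) == (len(small_hierarchy.nodes) + 1) * len(GRADE_LABELS)


class TestPublishedConsistency:
    def test_recombining_published_scores_reproduces_parents(self, xian_hierarchy, xian_scores):
        """Printed child scores x printed weights reproduce printed parent
        scores within the tables' own rounding slack."""
        for level in (2, 1):
            for node in xian_hierarchy.level_nodes(level):
                children = xian_hierarchy.children(node.id)
                recombined = (
                    sum(c.weight * xian_scores[c.id] for c in children) / node.weight
                )
                assert recombined == pytest.approx(xian_scores[node.id], abs=0.002), node.id
        roots = xian_hierarchy.level_nodes(1)
        overall = sum(r.weight * xian_scores[r.id] for r in roots)
        assert overall == pytest.approx(xian_scores["overall"], abs=0.002)
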