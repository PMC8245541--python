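"""Fold-change matrix construction and average-linkage (UPGMA) clustering."""

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bonlac import average_linkage_tree, build_fc_matrix, cut_tree
from bonlac.cluster import ClusterError

from conftest import make_table
from oracles import brute_force_average_linkage

NAN = float("nan")


class TestBuildFcMatrix:
    def two_cohorts(self):
        young = make_table(
            {
                "P1": [2.0, 2.0, 2.0],
                "P2": [1.0, 1.0, 1.0],
                "P3": [0.5, 0.5, NAN],
                "P4": [1.3, NAN, NAN],  # fails majority in young
            }
        )
        aged = make_table(
            {
                "P1": [0.5, 0.5, 0.5],
                "P2": [1.0, 1.0, 1.0],
                "P3": [2.0, 2.0, 2.0],
                "P4": [1.3, 1.3, 1.3],
            }
        )
        return {"young": young, "aged": aged}

    def test_majority_restriction_and_row_centering(self):
        m = build_fc_matrix(self.two_cohorts())
        # P4 not majority-detected in young -> excluded
        assert m.protein_ids == ["P1", "P2", "P3"]
        # cohort ratios {2.0, 0.5} center to {+1, -1} in log2
        assert m.values.loc["P1"].tolist() == pytest.approx([1.0, -1.0])
        assert m.values.loc["P3"].tolist() == pytest.approx([-1.0, 1.0])
        assert np.allclose(m.values.mean(axis=1), 0.0)

    def test_all_unit_ratios_give_zero_matrix(self):
        cohorts = {
            "a": make_table({"P1": [1.0, 1.0, 1.0]}),
            "b": make_table({"P1": [1.0, 1.0, 1.0]}),
        }
        m = build_fc_matrix(cohorts)
        assert (m.values.to_numpy() == 0.0).all()

    def test_hand_computed_log_values(self):
        """3 proteins x 2 cohorts equals hand-computed log2 minus row means."""
        cohorts = {
            "a": make_table({"P1": [2.0, 2.0], "P2": [4.0, 1.0], "P3": [0.5, 0.5]}),
            "b": make_table({"P1": [1.0, 1.0], "P2": [2.0, 2.0], "P3": [1.0, 1.0]}),
        }
        m = build_fc_matrix(cohorts)
        # P2 cohort a mean ratio = 2.5 -> log2 = 1.3219; cohort b -> 1.0
        expected = {
            "P1": [0.5, -0.5],
            "P2": [(np.log2(2.5) - 1.0) / 2, (1.0 - np.log2(2.5)) / 2],
            "P3": [-0.5, 0.5],
        }
        for pid, vals in expected.items():
            assert m.values.loc[pid].tolist() == pytest.approx(vals)

    def test_broad_window_is_annotation_not_filter(self):
        m = build_fc_matrix(self.two_cohorts(), broad_window=(0.85, 1.15))
        assert m.protein_ids == ["P1", "P2", "P3"]
        assert m.outside_broad_window.loc["P1"]
        assert not m.outside_broad_window.loc["P2"]

    def test_empty_intersection_is_error(self):
        cohorts = {
            "a": make_table({"P1": [1.0, 1.0]}),
            "b": make_table({"P2": [1.0, 1.0]}),
        }
        with pytest.raises(ClusterError, match="overlap is empty"):
            build_fc_matrix(cohorts)


class TestAverageLinkage:
    def test_identical_rows_merge_at_zero(self):
        tree = average_linkage_tree(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert tree.heights.tolist() == [0.0]

    def test_hand_derived_four_leaf_example(self):
        """1-D rows {0, 1, 5, 6.5}: merges at 1, 1.5 and 5.25."""
        tree = average_linkage_tree(np.array([0.0, 1.0, 5.0, 6.5]))
        assert tree.heights.tolist() == pytest.approx([1.0, 1.5, 5.25])
        assert set(tree.merges[0, :2]) == {0, 1}
        assert set(tree.merges[1, :2]) == {2, 3}

    def test_matches_brute_force_oracle(self, rng):
        """Merge order and heights equal exhaustive recomputation, n <= 8."""
        for _ in range(60):
            n = int(rng.integers(2, 9))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            mine = average_linkage_tree(X).merges
            oracle = brute_force_average_linkage(X)
            assert np.array_equal(mine[:, :2], oracle[:, :2])
            assert np.allclose(mine[:, 2], oracle[:, 2], rtol=1e-9, atol=0)

    def test_cross_check_against_scipy(self, rng):
        """Independent library cross-check on tie-free matrices."""
        for _ in range(20):
            X = rng.normal(size=(7, 3))
            mine = average_linkage_tree(X).merges
            ref = sch.linkage(X, method="average", metric="euclidean")
            assert np.allclose(mine[:, 2], ref[:, 2], rtol=1e-9)
            for row_mine, row_ref in zip(mine, ref):
                assert set(row_mine[:2]) == set(row_ref[:2])

    def test_tie_break_is_lexicographic(self):
        # four equidistant-pair points: (0,1) merges before (2,3)
        tree = average_linkage_tree(np.array([0.0, 1.0, 10.0, 11.0]))
        assert set(tree.merges[0, :2]) == {0, 1}
        assert set(tree.merges[1, :2]) == {2, 3}

    def test_nonfinite_rejected(self):
        with pytest.raises(ClusterError, match="non-finite"):
            average_linkage_tree(np.array([[1.0], [np.inf]]))

    def test_single_row_rejected(self):
        with pytest.raises(ClusterError):
            average_linkage_tree(np.array([[1.0, 2.0]]))


class TestClusterTreeProperties:
    matrices = hnp.arrays(
        dtype=float,
        shape=st.tuples(st.integers(2, 8), st.integers(1, 3)),
        elements=st.floats(-50, 50, allow_nan=False, width=32),
    )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(matrices)
    def test_oracle_equivalence_property(self, X):
        mine = average_linkage_tree(X).merges
        oracle = brute_force_average_linkage(X)
        assert np.array_equal(mine[:, :2], oracle[:, :2])
        assert np.allclose(mine[:, 2], oracle[:, 2], rtol=1e-9, atol=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(matrices, st.floats(0.1, 10))
    def test_scale_equivariance_and_monotone_heights(self, X, c):
        tree = average_linkage_tree(X)
        heights = tree.heights
        assert (np.diff(heights) >= -1e-12).all()  # average linkage: no inversions
        scaled = average_linkage_tree(c * X)
        assert np.array_equal(scaled.merges[:, :2], tree.merges[:, :2])
        assert np.allclose(scaled.heights, c * heights, rtol=1e-9, atol=1e-12)


class TestCutTree:
    @pytest.fixture
    def tree(self):
        return average_linkage_tree(
            np.array([0.0, 1.0, 5.0, 6.5]), labels=["a", "b", "c", "d"]
        )

    def test_k_equals_n(self, tree):
        assert cut_tree(tree, 4).nunique() == 4

    def test_k_equals_one(self, tree):
        assert cut_tree(tree, 1).nunique() == 1

    def test_k_two_splits_hand_example(self, tree):
        groups = cut_tree(tree, 2)
        assert groups["a"] == groups["b"]
        assert groups["c"] == groups["d"]
        assert groups["a"] != groups["c"]

    def test_k_out_of_range(self, tree):
        with pytest.raises(ClusterError):
            cut_tree(tree, 0)
        with pytest.raises(ClusterError):
            cut_tree(tree, 5)

    def test_every_leaf_in_exactly_one_group(self, rng):
        X = rng.normal(size=(12, 2))
        tree = average_linkage_tree(X)
        for k in (1, 3, 6, 12):
            groups = cut_tree(tree, k)
            assert len(groups) == 12
            assert groups.nunique() == k


class TestNewickExport:
    def test_round_trip_through_scikit_bio(self):
        """Exported Newick parses and preserves leaf set and ultrametric depths."""
        skbio = pytest.importorskip("skbio")
        tree = average_linkage_tree(
            np.array([0.0, 1.0, 5.0, 6.5]), labels=["a", "b", "c", "d"]
        )
        parsed = skbio.TreeNode.read([tree.to_newick()])
        assert {t.name for t in parsed.tips()} == {"a", "b", "c", "d"}
        # root-to-tip distance equals half the final merge height for every tip
        depths = {t.name: parsed.distance(t) for t in parsed.tips()}
        assert all(abs(d - 5.25 / 2) < 1e-12 for d in depths.values())
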