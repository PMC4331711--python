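"""Committee trees and 100%-frequency interval rule extraction."""

import numpy as np
import pytest

from connectedrules.io import ExpressionMatrix, LabelVector
from connectedrules.ranking import rank_features
from connectedrules.tree_rules import (
    IntervalCondition,
    Rule,
    build_tree,
    committee,
    extract_rules,
    rule_covers,
)
from conftest import brute_force_pure_pairs, verify_rule_exact


@pytest.fixture
def example_rule():
    return Rule(
        [
            IntervalCondition("m1", 8.94, 43.53),
            IntervalCondition("m2", 95.54, 1057.51),
        ],
        "HCV+",
        1.0,
        24,
        0,
    )


class TestRuleCovers:
    def test_inside(self, example_rule):
        assert rule_covers(example_rule, {"m1": 10.0, "m2": 100.0})

    def test_boundary_is_inclusive(self, example_rule):
        assert rule_covers(example_rule, {"m1": 8.94, "m2": 100.0})

    def test_just_outside(self, example_rule):
        assert not rule_covers(example_rule, {"m1": 8.93, "m2": 100.0})

    def test_missing_feature_is_error(self, example_rule):
        with pytest.raises(KeyError):
            rule_covers(example_rule, {"m1": 10.0})


def _xor_matrix():
    # asymmetric XOR-like layout: neither feature alone separates, but every
    # leaf of a depth-2 tree is pure
    values = np.array(
        [
            [1.0, 2.0, 9.0, 1.0, 9.0],
            [1.0, 2.0, 9.0, 9.0, 1.0],
        ]
    )
    labels = LabelVector(
        [f"s{i}" for i in range(5)], ["+", "+", "+", "-", "-"]
    )
    return ExpressionMatrix(["f1", "f2"], labels.sample_ids, values), labels


class TestBuildTree:
    def test_single_feature_separation_gives_depth_one(self, labels4):
        m = ExpressionMatrix(
            ["f1", "f2"],
            labels4.sample_ids,
            np.array([[1.0, 2.0, 9.0, 10.0], [5.0, 5.1, 5.0, 5.2]]),
        )
        tree = build_tree(m, labels4)
        assert tree.root_feature == "f1"
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        assert len(tree.root.left.class_counts) == 1
        assert len(tree.root.right.class_counts) == 1

    def test_xor_layout_needs_depth_two(self):
        m, labels = _xor_matrix()
        tree = build_tree(m, labels)
        assert not tree.root.is_leaf
        internal_children = [c for c in (tree.root.left, tree.root.right) if not c.is_leaf]
        assert internal_children  # at least one second-level split
        # every leaf at depth 2 must be pure for this layout
        for child in internal_children:
            for leaf in (child.left, child.right):
                assert len(leaf.class_counts) == 1

    def test_pure_noise_gives_tree_without_error(self):
        rng = np.random.default_rng(0)
        labels = LabelVector([f"s{i}" for i in range(10)], ["+"] * 5 + ["-"] * 5)
        m = ExpressionMatrix(["a", "b"], labels.sample_ids, rng.normal(0, 1, (2, 10)))
        build_tree(m, labels)  # impure leaves allowed


class TestCommittee:
    def test_roots_distinct_and_count_bounded(self, planted_data):
        trees = committee(planted_data.mirna, planted_data.labels)
        roots = [t.root_feature for t in trees if t.root_feature]
        assert len(roots) == len(set(roots))
        assert len(trees) <= planted_data.mirna.n_features - 1

    def test_two_features_one_tree(self):
        m, labels = _xor_matrix()
        assert len(committee(m, labels)) == 1

    def test_removing_non_root_feature_preserves_first_tree(self, planted_data):
        m, labels = planted_data.mirna, planted_data.labels
        t1 = build_tree(m, labels)
        non_root = [f for f in m.feature_ids if f != t1.root_feature][-1]
        m2 = m.subset_features([f for f in m.feature_ids if f != non_root])
        t2 = build_tree(m2, labels)
        assert t1.root_feature == t2.root_feature
        assert t1.root.threshold == t2.root.threshold


class TestExtractRules:
    def test_planted_pair_yields_verified_rules(self, planted_data):
        m, labels = planted_data.mirna, planted_data.labels
        ranked = rank_features(m, labels)
        top = m.subset_features([r.feature_id for r in ranked])
        rules = extract_rules(committee(top, labels), top, labels)
        assert rules
        signal = set(planted_data.truth.signal_mirnas)
        assert any(set(r.feature_ids) <= signal for r in rules)
        for r in rules:
            assert r.frequency == 1.0 and r.n_covered_other == 0
            assert verify_rule_exact(r, m, labels)

    def test_bounds_are_class_extremes(self):
        # replant the printed example bounds as the target-class extremes
        pos_f1 = np.array([8.94, 20.0, 30.0, 43.53])
        pos_f2 = np.array([95.54, 400.0, 800.0, 1057.51])
        neg_f1 = np.array([50.0, 60.0, 70.0, 80.0])
        neg_f2 = np.array([1.0, 2.0, 3.0, 4.0])
        labels = LabelVector(
            [f"s{i}" for i in range(8)], ["HCV+"] * 4 + ["HCV-"] * 4
        )
        m = ExpressionMatrix(
            ["miR-557", "miR-214"],
            labels.sample_ids,
            np.array([np.concatenate([pos_f1, neg_f1]), np.concatenate([pos_f2, neg_f2])]),
        )
        rules = extract_rules(committee(m, labels), m, labels)
        pos_rules = [r for r in rules if r.target_class == "HCV+"]
        assert pos_rules
        conds = {c.feature_id: c for c in pos_rules[0].conditions}
        assert conds["miR-557"].low == 8.94 and conds["miR-557"].high == 43.53
        assert conds["miR-214"].low == 95.54 and conds["miR-214"].high == 1057.51

    def test_pure_noise_usually_empty(self):
        rng = np.random.default_rng(1)
        labels = LabelVector([f"s{i}" for i in range(36)], ["+"] * 24 + ["-"] * 12)
        m = ExpressionMatrix(
            [f"n{i}" for i in range(8)], labels.sample_ids, rng.normal(0, 1, (8, 36))
        )
        rules = extract_rules(committee(m, labels), m, labels)
        assert rules == []

    def test_output_subset_of_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(20):
            n_feat = int(rng.integers(3, 9))
            n = int(rng.integers(8, 30))
            n_pos = int(rng.integers(3, n - 2))
            values = rng.normal(0, 1, (n_feat, n))
            if trial % 2 == 0:  # plant a separating shift on one feature
                values[0, :n_pos] += rng.uniform(1.5, 4.0)
            labels = LabelVector(
                [f"s{i}" for i in range(n)], ["+"] * n_pos + ["-"] * (n - n_pos)
            )
            m = ExpressionMatrix([f"f{i}" for i in range(n_feat)], labels.sample_ids, values)
            rules = extract_rules(committee(m, labels), m, labels)
            oracle = brute_force_pure_pairs(m, labels)
            for r in rules:
                assert frozenset(r.feature_ids) in oracle[r.target_class]
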