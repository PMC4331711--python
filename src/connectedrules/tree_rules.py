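"""Committee-of-decision-trees discovery of 100%-frequency interval rules.

A 100%-frequency rule is a conjunction of closed intervals, one per
feature, that covers every sample of one class and no sample of the other.
Trees are grown by recursive gain-ratio splitting; the committee is built
by repeatedly removing the previous tree's root feature and refitting, so
each tree explores a different part of the feature set.  Root-to-leaf
paths that isolate one class perfectly are converted to two-sided interval
rules by tightening each one-sided path test to the observed min/max of the
target class — the printed form discriminatory rules take in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .io import ExpressionMatrix, LabelVector
from .ranking import gain_ratio

__all__ = [
    "IntervalCondition",
    "Rule",
    "DecisionTree",
    "TreeNode",
    "rule_covers",
    "build_tree",
    "committee",
    "extract_rules",
]


@dataclass(frozen=True)
class IntervalCondition:
    """Closed interval condition ``low <= feature <= high``."""

    feature_id: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"{self.feature_id}: low {self.low} > high {self.high}")

    def holds(self, value: float) -> bool:
        return self.low <= value <= self.high


@dataclass
class Rule:
    """Conjunction of interval conditions targeting one class.

    ``frequency`` is the covered fraction of the target class; a
    100%-frequency rule has frequency 1.0 and covers zero other-class
    samples.
    """

    conditions: list[IntervalCondition]
    target_class: str
    frequency: float
    n_covered_target: int
    n_covered_other: int
    round: Optional[int] = None

    def __post_init__(self) -> None:
        feats = [c.feature_id for c in self.conditions]
        if len(set(feats)) != len(feats):
            raise ValueError(f"duplicate features in rule conditions: {feats}")

    @property
    def feature_ids(self) -> list[str]:
        return [c.feature_id for c in self.conditions]

    @property
    def k(self) -> int:
        return len(self.conditions)

    def key(self) -> tuple:
        return (frozenset(self.feature_ids), self.target_class)

    def to_dict(self) -> dict:
        d = {
            "class": self.target_class,
            "conditions": [
                {"feature": c.feature_id, "low": c.low, "high": c.high}
                for c in self.conditions
            ],
            "frequency": self.frequency,
            "n_covered_target": self.n_covered_target,
            "n_covered_other": self.n_covered_other,
        }
        if self.round is not None:
            d["round"] = self.round
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(
            conditions=[
                IntervalCondition(c["feature"], float(c["low"]), float(c["high"]))
                for c in d["conditions"]
            ],
            target_class=d["class"],
            frequency=float(d["frequency"]),
            n_covered_target=int(d["n_covered_target"]),
            n_covered_other=int(d["n_covered_other"]),
            round=d.get("round"),
        )


def rule_covers(rule: Rule, sample: Mapping[str, float]) -> bool:
    """True iff every condition holds for the sample (inclusive bounds)."""
    for cond in rule.conditions:
        if cond.feature_id not in sample:
            raise KeyError(f"sample is missing feature {cond.feature_id!r}")
        if not cond.holds(sample[cond.feature_id]):
            return False
    return True


@dataclass
class TreeNode:
    """Internal split (left branch = value <= threshold) or leaf."""

    feature_id: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    class_counts: dict[str, int] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature_id is None

    @property
    def majority_class(self) -> str:
        return max(sorted(self.class_counts), key=lambda c: self.class_counts[c])

    def predict_proba(self, sample: Mapping[str, float], cls: str) -> float:
        node = self
        while not node.is_leaf:
            node = node.left if sample[node.feature_id] <= node.threshold else node.right
        total = sum(node.class_counts.values())
        return node.class_counts.get(cls, 0) / total if total else 0.5


@dataclass
class DecisionTree:
    root: TreeNode

    @property
    def root_feature(self) -> Optional[str]:
        return self.root.feature_id


def _grow(
    values: np.ndarray,
    feature_ids: list[str],
    labels: list[str],
    label_vec: LabelVector,
    sample_idx: np.ndarray,
    depth: int,
    max_depth: int,
) -> TreeNode:
    sub_labels = [labels[i] for i in sample_idx]
    counts = {c: sub_labels.count(c) for c in label_vec.classes if c in sub_labels}
    node = TreeNode(class_counts=counts)
    if len(counts) < 2 or depth >= max_depth:
        return node

    sub_lv = LabelVector.__new__(LabelVector)  # bypass the ≥2-per-class check
    sub_lv.sample_ids = [label_vec.sample_ids[i] for i in sample_idx]
    sub_lv.labels = sub_labels

    best_gr, best_fi, best_thr = 0.0, None, None
    for fi, fid in enumerate(feature_ids):
        gr, thr = gain_ratio(values[fi, sample_idx], sub_lv)
        if gr <= 0:
            continue
        better = gr > best_gr + 1e-12
        tie_smaller_id = abs(gr - best_gr) <= 1e-12 and (
            best_fi is None or fid < feature_ids[best_fi]
        )
        if best_fi is None or better or tie_smaller_id:
            best_gr, best_fi, best_thr = gr, fi, thr
    if best_fi is None:
        return node

    fi, thr = best_fi, best_thr
    go_left = values[fi, sample_idx] <= thr
    left_idx, right_idx = sample_idx[go_left], sample_idx[~go_left]
    if len(left_idx) == 0 or len(right_idx) == 0:
        return node
    node.feature_id = feature_ids[fi]
    node.threshold = thr
    node.left = _grow(values, feature_ids, labels, label_vec, left_idx, depth + 1, max_depth)
    node.right = _grow(values, feature_ids, labels, label_vec, right_idx, depth + 1, max_depth)
    return node


def build_tree(matrix: ExpressionMatrix, labels: LabelVector, max_depth: int = 2) -> DecisionTree:
    """Grow a gain-ratio decision tree (depth-capped, no pruning).

    The default depth of 2 matches the focus on 2-feature rules.  Splitting
    stops when a node is pure or no split has positive gain.
    """
    labels = labels.aligned_to(matrix.sample_ids)
    root = _grow(
        matrix.values,
        matrix.feature_ids,
        list(labels.labels),
        labels,
        np.arange(matrix.n_samples),
        0,
        max_depth,
    )
    return DecisionTree(root)


def committee(
    matrix: ExpressionMatrix, labels: LabelVector, max_depth: int = 2
) -> list[DecisionTree]:
    """Build trees iteratively, removing each tree's root feature.

    The process repeats until only two features remain (the last tree is
    built on those two), or until a tree fails to split at all.
    """
    if matrix.n_features < 2:
        raise ValueError("committee requires at least 2 features")
    trees: list[DecisionTree] = []
    current = matrix
    while current.n_features >= 2:
        tree = build_tree(current, labels, max_depth=max_depth)
        trees.append(tree)
        if tree.root_feature is None:
            break
        remaining = [f for f in current.feature_ids if f != tree.root_feature]
        if len(remaining) < 2:
            break
        current = current.subset_features(remaining)
    return trees


def _paths(node: TreeNode, constraints: list) -> list[list]:
    if node.is_leaf:
        return [constraints]
    left = _paths(node.left, constraints + [(node.feature_id, "le", node.threshold)])
    right = _paths(node.right, constraints + [(node.feature_id, "gt", node.threshold)])
    return left + right


def extract_rules(
    trees: list[DecisionTree],
    matrix: ExpressionMatrix,
    labels: LabelVector,
    k: int = 2,
) -> list[Rule]:
    """Extract k-feature 100%-frequency rules from a tree committee.

    For every root-to-leaf path over at most `k` distinct features whose
    region contains all samples of one class and none of the other, an
    interval rule is emitted with bounds tightened to the target class's
    observed per-feature min/max.  A pure path shorter than `k` features
    (a single miRNA that separates the classes alone) is padded to `k` with
    the strongest remaining discriminators: adding a feature's class-range
    interval keeps every target-class sample and can only exclude more
    other-class samples, so purity is preserved.  Rules are mined for both
    classes and deduplicated on (feature set, class).
    """
    labels = labels.aligned_to(matrix.sample_ids)
    values = {fid: matrix.values[i] for i, fid in enumerate(matrix.feature_ids)}
    class_masks = {c: labels.mask(c) for c in labels.classes}

    ranked_ids = sorted(
        matrix.feature_ids,
        key=lambda f: (-gain_ratio(values[f], labels)[0], f),
    )
    rules: dict[tuple, Rule] = {}

    for tree in trees:
        for path in _paths(tree.root, []):
            feats = sorted({f for f, _, _ in path})
            if not feats or len(feats) > k:
                continue
            inside = np.ones(matrix.n_samples, dtype=bool)
            for f, op, thr in path:
                inside &= values[f] <= thr if op == "le" else values[f] > thr
            for cls in labels.classes:
                m = class_masks[cls]
                if not (inside[m].all() and not inside[~m].any()):
                    continue
                chosen = list(feats)
                for extra in ranked_ids:
                    if len(chosen) == k:
                        break
                    if extra not in chosen:
                        chosen.append(extra)
                if len(chosen) != k:
                    continue
                conds = [
                    IntervalCondition(f, float(values[f][m].min()), float(values[f][m].max()))
                    for f in sorted(chosen)
                ]
                rule = Rule(
                    conditions=conds,
                    target_class=cls,
                    frequency=1.0,
                    n_covered_target=int(m.sum()),
                    n_covered_other=0,
                )
                if _verify_pure(rule, values, m):
                    rules.setdefault(rule.key(), rule)
    return list(rules.values())


def _verify_pure(rule: Rule, values: dict[str, np.ndarray], target_mask: np.ndarray) -> bool:
    inside = np.ones(len(target_mask), dtype=bool)
    for cond in rule.conditions:
        v = values[cond.feature_id]
        inside &= (v >= cond.low) & (v <= cond.high)
    return bool(inside[target_mask].all() and not inside[~target_mask].any())
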