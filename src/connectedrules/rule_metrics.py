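"""Rule significance metrics: Max-Min class separation and 10-fold AUC.

The Max-Min distance of a rule is the smallest Euclidean distance between
any cross-class pair of samples, measured in the rule's own feature
subspace on raw expression values; a wider separation indicates a more
reliable rule.  The cross-validated AUC trains a small gain-ratio decision
tree on the rule's features per stratified fold and scores held-out
samples by leaf class probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionMatrix, LabelVector
from .tree_rules import Rule, build_tree

__all__ = ["RuleScore", "maxmin_distance", "cv_auc", "pearson", "score_rules"]


@dataclass
class RuleScore:
    rule_id: str
    maxmin_distance: float
    mean_auc: float


def maxmin_distance(rule: Rule, matrix: ExpressionMatrix, labels: LabelVector) -> float:
    """Minimum cross-class Euclidean distance in the rule's feature subspace."""
    labels = labels.aligned_to(matrix.sample_ids)
    sub = matrix.subset_features(rule.feature_ids)
    if sub.n_features != len(rule.feature_ids):
        missing = set(rule.feature_ids) - set(matrix.feature_ids)
        raise KeyError(f"rule features missing from matrix: {sorted(missing)}")
    pts = sub.values.T  # samples × features
    a = pts[labels.mask(labels.classes[0])]
    b = pts[labels.mask(labels.classes[1])]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both classes must be non-empty")
    return float(cdist(a, b).min())


def cv_auc(
    rule: Rule,
    matrix: ExpressionMatrix,
    labels: LabelVector,
    folds: int = 10,
    seed: int = 0,
    max_depth: int = 2,
) -> float:
    """Mean ROC AUC over seeded stratified k-fold CV on the rule's features.

    Folds whose test split contains a single class have undefined AUC and
    are excluded with a warning.  `folds` may not exceed the smaller class
    size (stratification would be impossible).
    """
    labels = labels.aligned_to(matrix.sample_ids)
    sub = matrix.subset_features(rule.feature_ids)
    y = np.array(labels.labels)
    min_class = min(labels.class_counts().values())
    if folds < 2 or folds > min_class:
        raise ValueError(
            f"folds={folds} must be between 2 and the smaller class size ({min_class})"
        )
    target = rule.target_class
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(sub.values.T, y):
        if len(set(y[test_idx])) < 2:
            warnings.warn("fold with a single class excluded from AUC averaging")
            continue
        train_m = sub.subset_samples([sub.sample_ids[i] for i in train_idx])
        train_lv = LabelVector.__new__(LabelVector)
        train_lv.sample_ids = train_m.sample_ids
        train_lv.labels = list(y[train_idx])
        tree = build_tree(train_m, train_lv, max_depth=max_depth)
        scores = []
        for i in test_idx:
            sample = {f: sub.values[j, i] for j, f in enumerate(sub.feature_ids)}
            scores.append(tree.root.predict_proba(sample, target))
        aucs.append(roc_auc_score(y[test_idx] == target, scores))
    if not aucs:
        raise ValueError("no fold produced a defined AUC")
    return float(np.mean(aucs))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; constant input is an error, not 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def score_rules(
    rules: list[Rule],
    matrix: ExpressionMatrix,
    labels: LabelVector,
    folds: int = 10,
    seed: int = 0,
) -> list[RuleScore]:
    """Max-Min distance and mean CV AUC for each rule (ids R1, R2, ...)."""
    return [
        RuleScore(
            rule_id=f"R{i}",
            maxmin_distance=maxmin_distance(rule, matrix, labels),
            mean_auc=cv_auc(rule, matrix, labels, folds=folds, seed=seed),
        )
        for i, rule in enumerate(rules, start=1)
    ]
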