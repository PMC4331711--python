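"""Multi-round greedy compactness mining of 100%-frequency mRNA rules.

For a target class c, each candidate attribute contributes the closed
interval spanned by c's samples among the currently active samples; its
compactness p = Nc/N is the class purity inside that interval.  The
greedy loop accepts the most compact attribute, restricts the active
sample set, and repeats until p = 1 (a rule) or p stops improving (no
rule).  Because intervals always span all of c's samples, every accepted
rule covers the full class: frequency is 1.0 by construction.

Mining runs in rounds: features consumed by accepted rules are removed
and both classes are retried until a round produces no rule at all.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .io import ExpressionMatrix, LabelVector
from .tree_rules import IntervalCondition, Rule

__all__ = ["class_range", "compactness", "mine_one_rule", "mine_all_rules"]


def class_range(
    values: np.ndarray, labels: LabelVector, cls: str, active: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """Min/max of the class's values among active samples (closed interval)."""
    values = np.asarray(values, dtype=float)
    mask = labels.mask(cls)
    if active is not None:
        mask = mask & active
    if not mask.any():
        raise ValueError(f"no active samples of class {cls!r}")
    v = values[mask]
    return float(v.min()), float(v.max())


def compactness(
    values: np.ndarray,
    labels: LabelVector,
    cls: str,
    bounds: tuple[float, float],
    active: Optional[np.ndarray] = None,
) -> float:
    """p = Nc/N inside the closed interval, over active samples."""
    values = np.asarray(values, dtype=float)
    low, high = bounds
    inside = (values >= low) & (values <= high)
    if active is not None:
        inside = inside & active
    n = int(inside.sum())
    if n == 0:
        raise ValueError("no samples inside bounds")
    nc = int((inside & labels.mask(cls)).sum())
    return nc / n


def mine_one_rule(
    matrix: ExpressionMatrix, labels: LabelVector, cls: str
) -> Optional[Rule]:
    """Greedy search for one 100%-frequency rule for class `cls`.

    Returns None when compactness cannot be strictly improved before
    reaching 1.0.  Ties between equally compact attributes go to the
    lexicographically smallest feature id.
    """
    labels = labels.aligned_to(matrix.sample_ids)
    cls_mask = labels.mask(cls)
    n_class = int(cls_mask.sum())
    active = np.ones(matrix.n_samples, dtype=bool)
    available = dict(zip(matrix.feature_ids, matrix.values))
    accepted: list[IntervalCondition] = []
    p = n_class / matrix.n_samples

    while p < 1.0 and available:
        best: Optional[tuple[float, str, tuple[float, float]]] = None
        for fid in available:
            bounds = class_range(available[fid], labels, cls, active)
            pf = compactness(available[fid], labels, cls, bounds, active)
            if best is None or pf > best[0] or (pf == best[0] and fid < best[1]):
                best = (pf, fid, bounds)
        if best is None or best[0] <= p:
            return None  # no strict improvement: plateau, no rule
        p, fid, bounds = best
        v = available.pop(fid)
        accepted.append(IntervalCondition(fid, bounds[0], bounds[1]))
        active = active & (v >= bounds[0]) & (v <= bounds[1])
    if p < 1.0:
        return None
    return Rule(
        conditions=accepted,
        target_class=cls,
        frequency=1.0,
        n_covered_target=n_class,
        n_covered_other=0,
    )


def mine_all_rules(
    matrix: ExpressionMatrix, labels: LabelVector, max_rounds: Optional[int] = None
) -> dict[str, list[Rule]]:
    """Round-based mining for both classes with feature removal.

    Per round, one rule is attempted per class on the matrix stripped of
    every feature used by any previously accepted rule; mining terminates
    when a round yields no rule for either class.  Rules carry their round
    number; feature sets across rules are pairwise disjoint.
    """
    labels = labels.aligned_to(matrix.sample_ids)
    rules: dict[str, list[Rule]] = {c: [] for c in labels.classes}
    used: set[str] = set()
    current = matrix
    round_no = 0
    while current.n_features > 0:
        round_no += 1
        if max_rounds is not None and round_no > max_rounds:
            break
        found_any = False
        consumed_this_round: set[str] = set()
        for cls in labels.classes:
            remaining = [f for f in current.feature_ids if f not in consumed_this_round]
            if not remaining:
                break
            rule = mine_one_rule(current.subset_features(remaining), labels, cls)
            if rule is not None:
                rule.round = round_no
                rules[cls].append(rule)
                consumed_this_round.update(rule.feature_ids)
                found_any = True
        if not found_any:
            break
        used.update(consumed_this_round)
        keep = [f for f in matrix.feature_ids if f not in used]
        if not keep:
            break
        current = matrix.subset_features(keep)
    return rules
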