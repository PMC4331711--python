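"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from connectedrules.io import ExpressionMatrix, LabelVector
from connectedrules.synthetic import SyntheticSpec, generate


@pytest.fixture
def labels4() -> LabelVector:
    return LabelVector(["s1", "s2", "s3", "s4"], ["neg", "neg", "pos", "pos"])


@pytest.fixture
def planted_data():
    """Default planted data set: 24+/12-, 4 signal miRNAs, 3 targets each."""
    return generate(SyntheticSpec(seed=11))


def pure_box_exists(values: np.ndarray, class_mask: np.ndarray, pair: tuple[int, int]) -> bool:
    """Oracle: is the class-min/max box on this feature pair 100%-frequency pure?"""
    i, j = pair
    box_ok = np.ones(values.shape[1], dtype=bool)
    for f in {i, j}:
        lo, hi = values[f, class_mask].min(), values[f, class_mask].max()
        box_ok &= (values[f] >= lo) & (values[f] <= hi)
    return bool(box_ok[class_mask].all() and not box_ok[~class_mask].any())


def brute_force_pure_pairs(
    matrix: ExpressionMatrix, labels: LabelVector
) -> dict[str, set[frozenset]]:
    """All feature pairs whose class-range box separates one class perfectly."""
    out: dict[str, set[frozenset]] = {c: set() for c in labels.classes}
    for cls in labels.classes:
        m = labels.mask(cls)
        for i, j in itertools.combinations(range(matrix.n_features), 2):
            if pure_box_exists(matrix.values, m, (i, j)):
                out[cls].add(frozenset({matrix.feature_ids[i], matrix.feature_ids[j]}))
    return out


def brute_force_rule_exists(matrix: ExpressionMatrix, labels: LabelVector, cls: str) -> bool:
    """Oracle: does any ≤2-condition class-range box perfectly isolate `cls`?"""
    m = labels.mask(cls)
    v = matrix.values
    # boolean "inside the class range" per feature × sample, restricted to non-class
    lo = v[:, m].min(axis=1, keepdims=True)
    hi = v[:, m].max(axis=1, keepdims=True)
    inside = (v >= lo) & (v <= hi)
    other = inside[:, ~m].astype(int)
    overlap = other @ other.T  # [i, j] = # non-class samples inside both ranges
    return bool((overlap == 0).any())


def random_two_class_matrix(
    rng: np.random.Generator, plant_pair: bool
) -> tuple[ExpressionMatrix, LabelVector]:
    """Random matrix (≤12 features × ≤40 samples), optionally with a planted
    pair of partially class-shifted features."""
    n_feat = int(rng.integers(3, 13))
    n_pos = int(rng.integers(3, 21))
    n_neg = int(rng.integers(3, 21))
    n = n_pos + n_neg
    values = rng.normal(0, 1, (n_feat, n))
    if plant_pair:
        shift = rng.uniform(0.8, 3.0, 2)
        f1, f2 = rng.choice(n_feat, 2, replace=False)
        values[f1, :n_pos] += shift[0]
        values[f2, :n_pos] -= shift[1]
    matrix = ExpressionMatrix(
        [f"f{i}" for i in range(n_feat)], [f"s{i}" for i in range(n)], values
    )
    labels = LabelVector(matrix.sample_ids, ["pos"] * n_pos + ["neg"] * n_neg)
    return matrix, labels


def verify_rule_exact(rule, matrix: ExpressionMatrix, labels: LabelVector) -> bool:
    """Independent 100%-frequency check: all target samples in, all others out."""
    inside = np.ones(matrix.n_samples, dtype=bool)
    for cond in rule.conditions:
        v = matrix.row(cond.feature_id)
        inside &= (v >= cond.low) & (v <= cond.high)
    m = labels.mask(rule.target_class)
    return bool(inside[m].all() and not inside[~m].any())
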