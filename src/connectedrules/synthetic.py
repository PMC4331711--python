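"""Synthetic paired miRNA/mRNA data with planted, recoverable structure.

The generator emulates a two-class paired expression study: a small set of
signal miRNAs whose class-conditional means differ by `class_gap` (so any
pair of them admits a 100%-frequency interval rule when the within-class
noise is small), target mRNAs linearly coupled to their regulator miRNA
with a chosen sign and slope, pure-noise features in both matrices, a
target map linking signal miRNAs to planted targets plus decoys, and UTR
sequences carrying seed-complementary sites at recorded positions.

Defaults mirror a 24/12 two-class design with 4 signal miRNAs, 3 targets
each and coupling slope 0.9 of alternating sign, with a class gap 100×
the within-class noise — strong, cleanly separable structure suitable for
end-to-end recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .io import ExpressionMatrix, LabelVector, SequenceRecord, TargetMap

__all__ = ["SyntheticSpec", "SyntheticTruth", "SyntheticData", "generate"]

_RNA = ("A", "C", "G", "U")
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SyntheticSpec:
    n_pos: int = 24
    n_neg: int = 12
    n_signal_mirna: int = 4
    n_noise_mirna: int = 16
    targets_per_mirna: int = 3
    n_noise_mrna: int = 20
    decoys_per_mirna: int = 2
    coupling_slope: float = 0.9
    coupling_signs: Optional[tuple[int, ...]] = None  # per target index; default alternates -,+
    noise_sd: float = 0.1
    class_gap: float = 10.0
    seed_length: int = 7
    planted_mismatches: int = 1
    utr_length: int = 120
    class_names: tuple[str, str] = ("HCV+", "HCV-")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("each class needs at least 2 samples")
        if self.n_signal_mirna < 1:
            raise ValueError("need at least one signal miRNA")
        if self.targets_per_mirna < 1:
            raise ValueError("need at least one target per signal miRNA")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.class_gap < 0:
            raise ValueError("class_gap must be non-negative (0 = null, no class signal)")


class PlantedSite(NamedTuple):
    mirna_id: str
    sequence_id: str
    start: int  # 1-based inclusive
    mismatches: int


@dataclass
class SyntheticTruth:
    """Ground truth of the planted structure, for recovery checks."""

    signal_mirnas: list[str]
    couplings: list[tuple[str, str, int]]  # (miRNA, gene, sign)
    seeds: dict[str, str]  # miRNA id -> seed (positions 2-8 of the mature strand)
    sites: list[PlantedSite]


@dataclass
class SyntheticData:
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    labels: LabelVector
    target_map: TargetMap
    sequences: list[SequenceRecord]
    truth: SyntheticTruth

    def __iter__(self):
        return iter((self.mirna, self.mrna, self.labels, self.target_map, self.sequences))


def _plant_site(rng: np.random.Generator, seq: list[str], seed_str: str, n_mismatch: int) -> tuple[int, int]:
    """Write the seed's reverse complement into `seq`; returns (start0, mismatches)."""
    k = len(seed_str)
    site = [
        _COMPLEMENT[b] for b in reversed(seed_str)
    ]
    mismatched = 0
    if n_mismatch > 0:
        pos_choices = rng.choice(k, size=min(n_mismatch, k), replace=False)
        for p in np.atleast_1d(pos_choices):
            alternatives = [b for b in _RNA if b != site[p]]
            site[p] = alternatives[rng.integers(len(alternatives))]
            mismatched += 1
    start0 = int(rng.integers(0, len(seq) - k + 1))
    seq[start0 : start0 + k] = site
    return start0, mismatched


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Deterministically generate all five pipeline inputs plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pos + spec.n_neg
    pos_cls, neg_cls = spec.class_names
    sample_ids = [f"s{i + 1:02d}" for i in range(n)]
    labels = LabelVector(sample_ids, [pos_cls] * spec.n_pos + [neg_cls] * spec.n_neg)
    is_pos = np.array([1.0] * spec.n_pos + [0.0] * spec.n_neg)

    # signal miRNAs: class-shifted Gaussians; shift direction alternates
    signal_ids = [f"miR-S{i + 1:02d}" for i in range(spec.n_signal_mirna)]
    noise_ids = [f"miR-N{i + 1:02d}" for i in range(spec.n_noise_mirna)]
    mirna_rows = []
    for i in range(spec.n_signal_mirna):
        base = 5.0 + 2.0 * i
        direction = 1.0 if i % 2 == 0 else -1.0
        row = base + direction * spec.class_gap * is_pos + rng.normal(0, spec.noise_sd, n)
        mirna_rows.append(row)
    for _ in range(spec.n_noise_mirna):
        mirna_rows.append(rng.normal(0, 1, n))
    mirna = ExpressionMatrix(signal_ids + noise_ids, sample_ids, np.array(mirna_rows))

    # target mRNAs coupled to their regulator; decoy/noise mRNAs iid
    signs = spec.coupling_signs or tuple(
        -1 if j % 2 == 0 else 1 for j in range(spec.targets_per_mirna)
    )
    if len(signs) != spec.targets_per_mirna:
        raise ValueError("coupling_signs length must equal targets_per_mirna")
    gene_ids: list[str] = []
    mrna_rows = []
    couplings: list[tuple[str, str, int]] = []
    for i, mirna_id in enumerate(signal_ids):
        for j in range(spec.targets_per_mirna):
            gene = f"GENE-S{i + 1:02d}T{j + 1}"
            sign = int(signs[j])
            expr = sign * spec.coupling_slope * mirna.values[i] + rng.normal(
                0, spec.noise_sd, n
            )
            gene_ids.append(gene)
            mrna_rows.append(expr)
            couplings.append((mirna_id, gene, sign))
    noise_genes = [f"GENE-N{i + 1:02d}" for i in range(spec.n_noise_mrna)]
    for _ in noise_genes:
        mrna_rows.append(rng.normal(0, 1, n))
    mrna = ExpressionMatrix(gene_ids + noise_genes, sample_ids, np.array(mrna_rows))

    # target map: planted targets plus decoys from the noise genes
    mapping: dict[str, set[str]] = {}
    for i, mirna_id in enumerate(signal_ids):
        planted = {g for m, g, _ in couplings if m == mirna_id}
        decoys: set[str] = set()
        if spec.decoys_per_mirna and noise_genes:
            k = min(spec.decoys_per_mirna, len(noise_genes))
            decoys = {noise_genes[int(x)] for x in rng.choice(len(noise_genes), k, replace=False)}
        mapping[mirna_id] = planted | decoys
    target_map = TargetMap(mapping)

    # seeds and UTR sequences with planted complementary sites
    seeds = {
        mirna_id: "".join(_RNA[int(x)] for x in rng.integers(0, 4, spec.seed_length))
        for mirna_id in signal_ids
    }
    sequences: list[SequenceRecord] = []
    sites: list[PlantedSite] = []
    for mirna_id, gene, sign in couplings:
        region = "5UTR" if sign > 0 else "3UTR"
        seq = [_RNA[int(x)] for x in rng.integers(0, 4, spec.utr_length)]
        start0, mm = _plant_site(rng, seq, seeds[mirna_id], spec.planted_mismatches)
        sequences.append(SequenceRecord(gene, region, "".join(seq)))
        sites.append(PlantedSite(mirna_id, gene, start0 + 1, mm))

    truth = SyntheticTruth(
        signal_mirnas=signal_ids, couplings=couplings, seeds=seeds, sites=sites
    )
    return SyntheticData(mirna, mrna, labels, target_map, sequences, truth)
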