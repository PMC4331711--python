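"""Seed-site scanning with mismatches and first-order Markov significance.

A candidate binding site is a window on the sense strand of a UTR/CDS that
matches the reverse complement of a miRNA seed (Watson-Crick pairing only,
unless wobble is enabled) at up to a fixed number of mismatched positions.
Significance of a site is the probability of its k-mer under a first-order
Markov chain estimated from the scanned sequence itself: the chain starts
from the sequence's global base composition and multiplies the empirical
transition probabilities of adjacent bases.  A lower probability means the
observed complementarity is less likely by composition alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RNA_ALPHABET, SequenceRecord

__all__ = [
    "BASE_ORDER",
    "TransitionMatrix",
    "SeedMatch",
    "build_transition_matrix",
    "mm_probability",
    "reverse_complement",
    "scan_seed",
]

# Row/column order used in all outputs.
BASE_ORDER = ("A", "G", "U", "C")
_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}
_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


@dataclass
class TransitionMatrix:
    """Adjacent-base counts and row-stochastic transition probabilities.

    `composition` holds per-base counts of the source sequence of length
    `length`; count rows sum to the base's composition, minus one for the
    sequence's terminal base (which starts no transition).
    """

    counts: np.ndarray  # 4×4 int, rows = from-base in BASE_ORDER
    probs: np.ndarray  # 4×4 float, row-stochastic (zero rows flagged)
    composition: np.ndarray  # 4 ints in BASE_ORDER
    length: int
    zero_rows: tuple[str, ...] = ()

    @classmethod
    def from_counts(
        cls, counts: np.ndarray, composition: np.ndarray, length: int
    ) -> "TransitionMatrix":
        """Build from an externally supplied adjacent-pair count table."""
        counts = np.asarray(counts, dtype=int)
        composition = np.asarray(composition, dtype=int)
        if counts.shape != (4, 4) or composition.shape != (4,):
            raise ValueError("counts must be 4×4 and composition length 4")
        row_sums = counts.sum(axis=1)
        probs = np.zeros((4, 4), dtype=float)
        zero_rows = []
        for i in range(4):
            if row_sums[i] > 0:
                probs[i] = counts[i] / row_sums[i]
            else:
                zero_rows.append(BASE_ORDER[i])
        return cls(
            counts=counts,
            probs=probs,
            composition=composition,
            length=length,
            zero_rows=tuple(zero_rows),
        )

    def initial_prob(self, base: str) -> float:
        return float(self.composition[_BASE_INDEX[base]]) / self.length

    def transition_prob(self, b1: str, b2: str) -> float:
        return float(self.probs[_BASE_INDEX[b1], _BASE_INDEX[b2]])


@dataclass
class SeedMatch:
    """One seed-complementary site on the sense strand (1-based inclusive)."""

    mirna_id: str
    sequence_id: str
    region_tag: str
    start: int
    end: int
    mismatches: int
    site_sequence: str
    p_exact: float
    p_window: float


def build_transition_matrix(seq: SequenceRecord) -> TransitionMatrix:
    """Count adjacent base pairs and row-normalize to probabilities."""
    s = seq.sequence
    if len(s) < 2:
        raise ValueError(f"sequence {seq.id!r} too short for transitions (length {len(s)})")
    counts = np.zeros((4, 4), dtype=int)
    for b1, b2 in zip(s, s[1:]):
        counts[_BASE_INDEX[b1], _BASE_INDEX[b2]] += 1
    composition = np.array([s.count(b) for b in BASE_ORDER], dtype=int)
    row_sums = counts.sum(axis=1)
    probs = np.zeros((4, 4), dtype=float)
    zero_rows = []
    for i in range(4):
        if row_sums[i] > 0:
            probs[i] = counts[i] / row_sums[i]
        else:
            zero_rows.append(BASE_ORDER[i])
    return TransitionMatrix(
        counts=counts,
        probs=probs,
        composition=composition,
        length=len(s),
        zero_rows=tuple(zero_rows),
    )


def mm_probability(kmer: str, tm: TransitionMatrix) -> float:
    """First-order Markov probability of a k-mer.

    p = (composition[c1]/L) × Π probs[c_i][c_(i+1)].  A transition with
    zero estimated probability yields 0.
    """
    kmer = kmer.upper().replace("T", "U")
    if len(kmer) < 1:
        raise ValueError("k-mer must be non-empty")
    bad = set(kmer) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid bases in k-mer: {sorted(bad)}")
    p = tm.initial_prob(kmer[0])
    for b1, b2 in zip(kmer, kmer[1:]):
        p *= tm.transition_prob(b1, b2)
        if p == 0.0:
            return 0.0
    return p


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _pairs(seed_base: str, window_base: str, allow_wobble: bool) -> bool:
    if _COMPLEMENT[seed_base] == window_base:
        return True
    return allow_wobble and (seed_base, window_base) in _WOBBLE_PAIRS


def scan_seed(
    mirna_seed: str,
    seq: SequenceRecord,
    max_mismatch: int = 1,
    mirna_id: str = "",
    allow_wobble: bool = False,
) -> list[SeedMatch]:
    """Find seed-complementary windows with up to `max_mismatch` mismatches.

    The seed (5'→3') binds antiparallel, so a perfect site equals the
    seed's reverse complement on the sense strand.  Coordinates are 1-based
    inclusive.  Each match is annotated with the Markov probability of its
    own genomic window (p_exact) and the probability of at least one
    occurrence of that window across the sequence (p_window).
    """
    seed = mirna_seed.upper().replace("T", "U")
    bad = set(seed) - RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid bases in seed: {sorted(bad)}")
    k = len(seed)
    if not 6 <= k <= 8:
        raise ValueError(f"seed length must be 6-8 nt, got {k}")
    s = seq.sequence
    if len(s) < k:
        return []
    tm = build_transition_matrix(seq) if len(s) >= 2 else None
    seed_rev = seed[::-1]  # seed position aligned with window position i is seed_rev[i]
    L = len(s)
    matches: list[SeedMatch] = []
    for start0 in range(L - k + 1):
        window = s[start0 : start0 + k]
        mism = sum(
            0 if _pairs(sb, wb, allow_wobble) else 1 for sb, wb in zip(seed_rev, window)
        )
        if mism <= max_mismatch:
            p_exact = mm_probability(window, tm)
            p_window = 1.0 - (1.0 - p_exact) ** (L - k + 1)
            matches.append(
                SeedMatch(
                    mirna_id=mirna_id,
                    sequence_id=seq.id,
                    region_tag=seq.region_tag,
                    start=start0 + 1,
                    end=start0 + k,
                    mismatches=mism,
                    site_sequence=window,
                    p_exact=p_exact,
                    p_window=p_window,
                )
            )
    return matches
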