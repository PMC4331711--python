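"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the in-memory types defined here:
:class:`ExpressionMatrix`, :class:`LabelVector`, :class:`TargetMap` and
:class:`SequenceRecord`.  Parsing is strict — duplicate identifiers,
non-numeric cells and missing labels are hard errors, because the
100%-frequency rule definition is meaningless on silently-repaired data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ExpressionMatrix",
    "LabelVector",
    "TargetMap",
    "SequenceRecord",
    "FormatError",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_target_map",
    "write_target_map",
    "read_fasta",
    "write_fasta",
    "read_rules",
    "write_rules",
    "write_network",
]

VALID_REGIONS = ("5UTR", "3UTR", "CDS")
RNA_ALPHABET = frozenset("ACGU")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class ExpressionMatrix:
    """Numeric features × samples matrix with ordered, unique identifiers.

    Values are kept in the units supplied; no rescaling or log transform is
    applied (any such preprocessing belongs upstream of this tool).
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # rows = features, cols = samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.feature_ids)) != len(self.feature_ids):
            dupes = _duplicates(self.feature_ids)
            raise FormatError(f"duplicate feature ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise FormatError(f"duplicate sample ids: {sorted(dupes)}")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features × {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            r, c = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, feature_id: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None
        return self.values[i]

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given features, preserving this matrix's order."""
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx], list(self.sample_ids), self.values[idx]
        )

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to the given samples, in the order of `keep`."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in keep]
        return ExpressionMatrix(list(self.feature_ids), list(keep), self.values[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class LabelVector:
    """Per-sample class labels drawn from exactly two class names."""

    sample_ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.labels):
            raise FormatError("sample_ids and labels differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError(f"duplicate sample ids: {sorted(_duplicates(self.sample_ids))}")
        classes = self.classes
        if len(classes) != 2:
            raise FormatError(f"expected exactly two classes, got {list(classes)}")
        for c in classes:
            if self.labels.count(c) < 2:
                raise FormatError(f"class {c!r} has fewer than 2 samples")

    @property
    def classes(self) -> tuple[str, str]:
        """The two class names in first-seen order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return tuple(seen)  # type: ignore[return-value]

    def mask(self, cls: str) -> np.ndarray:
        if cls not in self.classes:
            raise KeyError(f"unknown class {cls!r}")
        return np.array([lab == cls for lab in self.labels], dtype=bool)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.classes}

    def aligned_to(self, sample_ids: Sequence[str]) -> "LabelVector":
        """Reorder to match `sample_ids`; error on unknown/missing samples."""
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise FormatError(f"samples without labels: {missing}")
        return LabelVector(list(sample_ids), [lookup[s] for s in sample_ids])


@dataclass
class TargetMap:
    """miRNA id → set of predicted target gene ids."""

    mapping: dict[str, set[str]]

    def __post_init__(self) -> None:
        for mirna, targets in self.mapping.items():
            if not targets:
                raise FormatError(f"miRNA {mirna!r} has an empty target set")

    def targets_of(self, mirna: str) -> set[str]:
        if mirna not in self.mapping:
            raise KeyError(f"miRNA {mirna!r} not present in the target map")
        return self.mapping[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.mapping


@dataclass
class SequenceRecord:
    """One transcript region (5'UTR, 3'UTR or CDS) as an RNA string.

    DNA input (T) is normalized to RNA (U) at parse time.
    """

    id: str
    region_tag: str
    sequence: str

    def __post_init__(self) -> None:
        if self.region_tag not in VALID_REGIONS:
            raise FormatError(
                f"unknown region tag {self.region_tag!r} for {self.id!r}; "
                f"expected one of {VALID_REGIONS}"
            )
        seq = self.sequence.upper().replace("T", "U")
        if len(seq) < 1:
            raise FormatError(f"empty sequence for {self.id!r}")
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise FormatError(f"invalid characters {sorted(bad)} in sequence {self.id!r}")
        self.sequence = seq

    def __len__(self) -> int:
        return len(self.sequence)


def _duplicates(items: Iterable[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def _detect_sep(path: Path, dialect: str | None) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if dialect is not None:
        raise FormatError(f"unknown dialect {dialect!r}")
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_expression(path: str | Path, dialect: str | None = None) -> ExpressionMatrix:
    """Read a features × samples expression table.

    First row holds sample ids, first column feature ids.  The delimiter is
    auto-detected from the extension (.tsv/.tab/.txt → tab, otherwise comma)
    and can be forced with `dialect` ∈ {"tsv", "csv"}.
    """
    path = Path(path)
    sep = _detect_sep(path, dialect)
    try:
        # round_trip parsing so write→read is bit-identical
        df = pd.read_csv(path, sep=sep, index_col=0, header=0, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty expression file: {path}") from None
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"expression file has no data rows/columns: {path}")
    feature_ids = [str(f) for f in df.index]
    sample_ids = [str(s) for s in df.columns]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise FormatError(f"non-numeric value at feature {row!r}, sample {col!r}")
        if coerced.isna().any():
            row = df.index[coerced.isna().argmax()]
            raise FormatError(f"missing value at feature {row!r}, sample {col!r}")
        df[col] = coerced
    return ExpressionMatrix(feature_ids, sample_ids, df.to_numpy(dtype=float))


def write_expression(matrix: ExpressionMatrix, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _detect_sep(path, dialect)
    matrix.to_frame().to_csv(path, sep=sep, index_label="id")


def read_labels(path: str | Path) -> LabelVector:
    """Read a two-column sample_id,label file (no header)."""
    path = Path(path)
    sep = _detect_sep(path, None)
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty label file: {path}") from None
    if df.shape[1] != 2:
        raise FormatError(f"label file must have 2 columns, got {df.shape[1]}")
    return LabelVector(list(df[0].astype(str)), list(df[1].astype(str)))


def write_labels(labels: LabelVector, path: str | Path) -> None:
    path = Path(path)
    sep = _detect_sep(path, None)
    with open(path, "w") as fh:
        for s, lab in zip(labels.sample_ids, labels.labels):
            fh.write(f"{s}{sep}{lab}\n")


def read_target_map(path: str | Path) -> TargetMap:
    """Read a two-column TSV of (miRNA id, target gene id) pairs.

    Duplicate rows are allowed and deduplicated (set semantics). Lines
    starting with '#' are ignored, as is a TargetScan-style header line.
    """
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
            mirna, gene = parts[0].strip(), parts[1].strip()
            if lineno == 1 and mirna.lower() in {"mirna", "mir family", "mirna_id"}:
                continue  # header
            mapping.setdefault(mirna, set()).add(gene)
            n_rows += 1
    if not mapping:
        raise FormatError(f"empty target map: {path}")
    return TargetMap(mapping)


def write_target_map(target_map: TargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mirna in sorted(target_map.mapping):
            for gene in sorted(target_map.mapping[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def read_fasta(path: str | Path, default_region: str = "3UTR") -> list[SequenceRecord]:
    """Read FASTA records with headers of the form ``id|region``.

    The region tag is one of 5UTR/3UTR/CDS; when absent the record defaults
    to 3UTR (the canonical miRNA binding region).
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.id
        if "|" in header:
            seq_id, _, region = header.partition("|")
            if not seq_id or region not in VALID_REGIONS:
                raise FormatError(f"malformed FASTA header {header!r}")
        else:
            seq_id, region = header, default_region
        records.append(SequenceRecord(seq_id, region, str(rec.seq)))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}|{rec.region_tag}\n{rec.sequence}\n")


def write_rules(rules: Sequence, path: str | Path) -> None:
    """Serialize rules to structured JSON text (lossless round-trip)."""
    payload = [r.to_dict() for r in rules]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_rules(path: str | Path) -> list:
    from .tree_rules import Rule  # deferred: avoids a module cycle

    with open(path) as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise FormatError(f"rule file {path} must contain a JSON list")
    return [Rule.from_dict(d) for d in payload]


def write_network(network, path: str | Path, format: str = "sif") -> None:
    """Write an interaction network as SIF or a 3-column edge list.

    SIF rows are ``miRNA<TAB>regulates<TAB>mRNA`` (plus ``corule`` rows for
    miRNAs that co-occur in one discriminatory rule); the edge list carries
    the Pearson correlation as a third column.
    """
    if format not in {"sif", "edgelist"}:
        raise FormatError(f"unknown network format {format!r}")
    with open(path, "w") as fh:
        if format == "sif":
            for m, g in sorted(network.edges):
                fh.write(f"{m}\tregulates\t{g}\n")
            for a, b in sorted(network.corule_edges):
                fh.write(f"{a}\tcorule\t{b}\n")
        else:
            for m, g in sorted(network.edges):
                r = network.edge_data[(m, g)].get("pearson_r")
                fh.write(f"{m}\t{g}\t{'' if r is None else f'{r:.6f}'}\n")
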