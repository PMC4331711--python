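"""End-to-end pipeline: simulate → rank → miRNA rules → scores → mRNA rules
→ modules → seed scan, with a manifest for reproducibility.

One global seed fans out to per-stage seeds by fixed offsets, so adding a
stage never perturbs the randomness of earlier stages.  Reruns with the
same config and seed are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import io as cio
from . import network as net
from .greedy_rules import mine_all_rules
from .ranking import rank_features
from .rule_metrics import cv_auc, maxmin_distance
from .seed_markov import build_transition_matrix, scan_seed, BASE_ORDER
from .synthetic import SyntheticSpec, generate
from .tree_rules import committee, extract_rules

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets
_SEED_SIMULATE = 0
_SEED_CV = 101


@dataclass
class PipelineConfig:
    """All paths and tunables; defaults are the method's stated settings."""

    out_dir: str = "connectedrules_out"
    mirna_expression: Optional[str] = None
    mrna_expression: Optional[str] = None
    labels: Optional[str] = None
    target_map: Optional[str] = None
    fasta: Optional[str] = None
    seeds_file: Optional[str] = None  # 2-column TSV: miRNA id, seed (5'->3')
    simulate: bool = False
    gr_cutoff: float = 0.5
    max_k: int = 2
    folds: int = 10
    top_rules_per_class: int = 2
    min_regulators: int = 3
    max_mismatch: int = 1
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def _require(stage: str, path: Optional[str], what: str) -> Path:
    if path is None:
        raise StageError(stage, f"missing required input: {what}")
    p = Path(path)
    if not p.exists():
        raise StageError(stage, f"{what} not found: {p}")
    return p


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to out_dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "artifacts": {},
    }

    # stage 1: inputs (simulated or read from disk)
    if config.simulate:
        data = generate(SyntheticSpec(seed=config.seed + _SEED_SIMULATE))
        mirna, mrna, labels, target_map, sequences = data
        cio.write_expression(mirna, out / "mirna.tsv")
        cio.write_expression(mrna, out / "mrna.tsv")
        cio.write_labels(labels, out / "labels.csv")
        cio.write_target_map(target_map, out / "targets.tsv")
        cio.write_fasta(sequences, out / "utrs.fasta")
        seeds = data.truth.seeds
        with open(out / "seeds.tsv", "w") as fh:
            for m, s in sorted(seeds.items()):
                fh.write(f"{m}\t{s}\n")
        for key in ("mirna.tsv", "mrna.tsv", "labels.csv", "targets.tsv", "utrs.fasta", "seeds.tsv"):
            manifest["artifacts"][key] = str(out / key)
    else:
        mirna = cio.read_expression(_require("inputs", config.mirna_expression, "miRNA expression"))
        mrna = cio.read_expression(_require("inputs", config.mrna_expression, "mRNA expression"))
        labels = cio.read_labels(_require("inputs", config.labels, "labels"))
        target_map = cio.read_target_map(_require("inputs", config.target_map, "target map"))
        sequences = (
            cio.read_fasta(_require("inputs", config.fasta, "FASTA")) if config.fasta else []
        )
        seeds = {}
        if config.seeds_file:
            with open(_require("inputs", config.seeds_file, "seeds file")) as fh:
                for line in fh:
                    if line.strip():
                        m, s = line.split("\t")[:2]
                        seeds[m.strip()] = s.strip()
    labels = labels.aligned_to(mirna.sample_ids)
    manifest["stages"]["inputs"] = {
        "n_mirna": mirna.n_features,
        "n_mrna": mrna.n_features,
        "n_samples": mirna.n_samples,
        "class_counts": labels.class_counts(),
    }

    # stage 2: gain-ratio ranking
    ranked = rank_features(mirna, labels, gr_cutoff=config.gr_cutoff)
    with open(out / "ranked.tsv", "w") as fh:
        fh.write("id\trank\tgain_ratio\tthreshold\tp_value\n")
        for r in ranked:
            fh.write(f"{r.feature_id}\t{r.rank}\t{r.gain_ratio:.6f}\t{r.best_threshold:.6f}\t{r.p_value:.4g}\n")
    manifest["artifacts"]["ranked.tsv"] = str(out / "ranked.tsv")
    manifest["stages"]["rank"] = {"n_ranked": len(ranked)}
    if len(ranked) < 2:
        raise StageError("rank", f"only {len(ranked)} features pass gain-ratio cutoff {config.gr_cutoff}; need ≥2")

    # stage 3: committee trees and miRNA rules
    top_matrix = mirna.subset_features([r.feature_id for r in ranked])
    trees = committee(top_matrix, labels, max_depth=config.max_k)
    mirna_rules = extract_rules(trees, top_matrix, labels, k=config.max_k)
    mirna_rules.sort(key=lambda r: (labels.classes.index(r.target_class), sorted(r.feature_ids)))
    cio.write_rules(mirna_rules, out / "mirna_rules.json")
    manifest["artifacts"]["mirna_rules.json"] = str(out / "mirna_rules.json")
    manifest["stages"]["mirna_rules"] = {
        "n_trees": len(trees),
        "n_rules": len(mirna_rules),
    }
    if not mirna_rules:
        raise StageError("mirna_rules", "no 100%-frequency miRNA rules found")

    # stage 4: rule scores (Max-Min distance + CV AUC); ids by distance, widest first
    scored = sorted(
        mirna_rules,
        key=lambda r: (-maxmin_distance(r, top_matrix, labels), sorted(r.feature_ids)),
    )
    with open(out / "rule_scores.tsv", "w") as fh:
        fh.write("rule_id\tclass\tfeatures\tmaxmin_distance\tmean_auc\n")
        for i, rule in enumerate(scored, start=1):
            dist = maxmin_distance(rule, top_matrix, labels)
            auc = cv_auc(rule, top_matrix, labels, folds=config.folds, seed=config.seed + _SEED_CV)
            fh.write(
                f"R{i}\t{rule.target_class}\t{'+'.join(rule.feature_ids)}\t{dist:.4f}\t{auc:.4f}\n"
            )
    manifest["artifacts"]["rule_scores.tsv"] = str(out / "rule_scores.tsv")
    manifest["stages"]["score_rules"] = {"n_scored": len(scored)}

    # stage 5+6: per-rule mRNA rules and regulatory modules
    modules = []
    mrna_rule_counts = {}
    for i, rule in enumerate(scored, start=1):
        module_id = f"R{i}"
        try:
            selected_matrix = net.filter_targets(rule, target_map, mrna)
        except (KeyError, ValueError) as exc:
            raise StageError("mrna_rules", str(exc)) from exc
        by_class = mine_all_rules(selected_matrix, labels)
        cio.write_rules(
            [r for rules in by_class.values() for r in rules], out / f"mrna_rules_{module_id}.json"
        )
        mrna_rule_counts[module_id] = {c: len(rs) for c, rs in by_class.items()}
        top = net.select_top_rules(by_class, limit_per_class=config.top_rules_per_class)
        modules.append(net.build_module(module_id, rule, top, target_map, mirna, mrna))
    with open(out / "modules.json", "w") as fh:
        json.dump([m.to_dict() for m in modules], fh, indent=2)
        fh.write("\n")
    manifest["artifacts"]["modules.json"] = str(out / "modules.json")
    manifest["stages"]["mrna_rules"] = mrna_rule_counts

    network = net.merge_network(modules)
    cio.write_network(network, out / "network.sif", format="sif")
    cio.write_network(network, out / "network_edges.tsv", format="edgelist")
    core = net.many_to_many(network, min_regulators=config.min_regulators)
    cio.write_network(core, out / "many_to_many.sif", format="sif")
    manifest["artifacts"]["network.sif"] = str(out / "network.sif")
    manifest["artifacts"]["network_edges.tsv"] = str(out / "network_edges.tsv")
    manifest["artifacts"]["many_to_many.sif"] = str(out / "many_to_many.sif")
    manifest["stages"]["modules"] = {
        "n_modules": len(modules),
        "n_edges": len(network.edges),
        "n_many_to_many_mrnas": len(core.mrna_nodes),
    }

    # stage 7: seed scanning (only when sequences and seeds are available)
    if sequences and seeds:
        with open(out / "seed_matches.tsv", "w") as fh:
            fh.write("mirna\tsequence\tregion\tstart\tend\tmismatches\tsite\tp_exact\tp_window\n")
            n_matches = 0
            for mirna_id, seed_str in sorted(seeds.items()):
                for seq in sequences:
                    for m in scan_seed(seed_str, seq, max_mismatch=config.max_mismatch, mirna_id=mirna_id):
                        fh.write(
                            f"{m.mirna_id}\t{m.sequence_id}\t{m.region_tag}\t{m.start}\t{m.end}"
                            f"\t{m.mismatches}\t{m.site_sequence}\t{m.p_exact:.4g}\t{m.p_window:.4g}\n"
                        )
                        n_matches += 1
        manifest["artifacts"]["seed_matches.tsv"] = str(out / "seed_matches.tsv")
        manifest["stages"]["seed_scan"] = {"n_matches": n_matches}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def write_transition_matrix_tsv(seq_record, path: str | Path) -> None:
    """Export a sequence's transition matrix as counts with 3-decimal probabilities."""
    tm = build_transition_matrix(seq_record)
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(BASE_ORDER) + "\tSum\n")
        for i, b in enumerate(BASE_ORDER):
            cells = [
                f"{tm.counts[i, j]} ({tm.probs[i, j]:.3f})" for j in range(4)
            ]
            fh.write(f"{b}\t" + "\t".join(cells) + f"\t{tm.counts[i].sum()}\n")
        fh.write("Sum\t" + "\t".join(str(int(c)) for c in tm.composition) + f"\t{tm.length}\n")
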