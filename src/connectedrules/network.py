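"""Bipartite miRNA-mRNA regulatory modules and their merged network.

Each discriminatory miRNA rule seeds one module: the mRNA matrix is first
restricted to the predicted targets of the rule's miRNAs, 100%-frequency
mRNA rules are mined there, the top rules per class are selected, and
edges are drawn from each miRNA to the selected mRNAs it is predicted to
target, annotated with the Pearson correlation over paired samples.
Modules merge into a single bipartite interaction network; mRNAs hit by
several distinct miRNAs form the many-to-many core.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .io import ExpressionMatrix, LabelVector, TargetMap
from .rule_metrics import pearson
from .tree_rules import Rule

__all__ = [
    "RegulatoryModule",
    "InteractionNetwork",
    "filter_targets",
    "select_top_rules",
    "build_module",
    "merge_network",
    "many_to_many",
]

logger = logging.getLogger(__name__)


@dataclass
class RegulatoryModule:
    """One miRNA rule, its selected mRNA rules and the bipartite edges."""

    module_id: str
    mirna_rule: Rule
    mrna_rules: list[Rule]
    edges: list[tuple[str, str, Optional[float]]]  # (miRNA, mRNA, pearson_r)

    def to_dict(self) -> dict:
        return {
            "module_id": self.module_id,
            "mirna_rule": self.mirna_rule.to_dict(),
            "mrna_rules": [r.to_dict() for r in self.mrna_rules],
            "edges": [
                {"mirna": m, "mrna": g, "pearson_r": r} for m, g, r in self.edges
            ],
        }


@dataclass
class InteractionNetwork:
    """Merged bipartite network; edges carry correlation and source modules."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    corule_edges: set[tuple[str, str]] = field(default_factory=set)

    @property
    def mirna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("bipartite") == 0}

    @property
    def mrna_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d.get("bipartite") == 1}

    @property
    def edges(self) -> set[tuple[str, str]]:
        out = set()
        for u, v in self.graph.edges:
            if self.graph.nodes[u].get("bipartite") == 0:
                out.add((u, v))
            else:
                out.add((v, u))
        return out

    @property
    def edge_data(self) -> dict[tuple[str, str], dict]:
        return {e: dict(self.graph.edges[e]) for e in self.edges}

    def is_bipartite(self) -> bool:
        return all(
            self.graph.nodes[u].get("bipartite") != self.graph.nodes[v].get("bipartite")
            for u, v in self.graph.edges
        )


def filter_targets(
    mirna_rule: Rule, target_map: TargetMap, mrna_matrix: ExpressionMatrix
) -> ExpressionMatrix:
    """Restrict the mRNA matrix to the rule's predicted targets.

    Keeps the union of targets of every miRNA in the rule that are present
    among the matrix features; all samples are retained.  Idempotent.
    """
    union: set[str] = set()
    for mirna in mirna_rule.feature_ids:
        union |= target_map.targets_of(mirna)
    present = [f for f in mrna_matrix.feature_ids if f in union]
    if not present:
        raise ValueError(
            f"no predicted targets of rule on {mirna_rule.feature_ids} "
            "are present in the mRNA matrix"
        )
    return mrna_matrix.subset_features(present)


def select_top_rules(
    rules_by_class: dict[str, list[Rule]], limit_per_class: int = 2
) -> list[Rule]:
    """Up to `limit_per_class` rules per class.

    Ordered by (mining round ascending, number of conditions ascending,
    feature ids lexicographic) — earlier rounds consume the most compact
    attributes, so they come first.
    """
    selected: list[Rule] = []
    for cls in rules_by_class:
        ordered = sorted(
            rules_by_class[cls],
            key=lambda r: (r.round if r.round is not None else 0, r.k, sorted(r.feature_ids)),
        )
        selected.extend(ordered[:limit_per_class])
    return selected


def build_module(
    module_id: str,
    mirna_rule: Rule,
    selected_mrna_rules: list[Rule],
    target_map: TargetMap,
    paired_mirna_matrix: ExpressionMatrix,
    paired_mrna_matrix: ExpressionMatrix,
) -> RegulatoryModule:
    """Bipartite module: edges from each rule miRNA to its targeted rule mRNAs.

    Pearson correlations are computed on the samples shared by both paired
    matrices; unpaired samples are excluded (their count is logged).  An
    mRNA appearing in a selected rule but targeted by neither miRNA stays in
    the rule listing but gets no edge.
    """
    shared = [s for s in paired_mirna_matrix.sample_ids if s in set(paired_mrna_matrix.sample_ids)]
    n_dropped = (
        len(paired_mirna_matrix.sample_ids) + len(paired_mrna_matrix.sample_ids) - 2 * len(shared)
    )
    if n_dropped:
        logger.info("module %s: %d unpaired sample columns excluded", module_id, n_dropped)
    mi = paired_mirna_matrix.subset_samples(shared) if shared else None
    mr = paired_mrna_matrix.subset_samples(shared) if shared else None

    rule_mrnas: list[str] = []
    for rule in selected_mrna_rules:
        for g in rule.feature_ids:
            if g not in rule_mrnas:
                rule_mrnas.append(g)

    edges: list[tuple[str, str, Optional[float]]] = []
    for mirna in mirna_rule.feature_ids:
        targets = target_map.targets_of(mirna)
        for g in rule_mrnas:
            if g not in targets:
                continue
            r: Optional[float] = None
            if mi is not None and mirna in mi.feature_ids and g in mr.feature_ids:
                try:
                    r = pearson(mi.row(mirna), mr.row(g))
                except ValueError:
                    r = None
            edges.append((mirna, g, r))
    return RegulatoryModule(module_id, mirna_rule, selected_mrna_rules, edges)


def merge_network(modules: list[RegulatoryModule]) -> InteractionNetwork:
    """Union of module edges, deduplicated, with source-module provenance."""
    if not modules:
        raise ValueError("at least one module is required")
    net = InteractionNetwork()
    g = net.graph
    for mod in modules:
        mirnas = mod.mirna_rule.feature_ids
        for a, b in zip(mirnas, mirnas[1:]):
            net.corule_edges.add((min(a, b), max(a, b)))
        for mirna, gene, r in mod.edges:
            g.add_node(mirna, bipartite=0)
            g.add_node(gene, bipartite=1)
            if g.has_edge(mirna, gene):
                g.edges[mirna, gene]["modules"].add(mod.module_id)
                if r is not None:
                    g.edges[mirna, gene]["pearson_r"] = r
            else:
                g.add_edge(mirna, gene, pearson_r=r, modules={mod.module_id})
    return net


def many_to_many(network: InteractionNetwork, min_regulators: int = 3) -> InteractionNetwork:
    """Sub-network of mRNAs regulated by at least `min_regulators` miRNAs."""
    keep_mrnas = {
        g for g in network.mrna_nodes if network.graph.degree(g) >= min_regulators
    }
    sub = InteractionNetwork(corule_edges=set(network.corule_edges))
    for m, g in network.edges:
        if g in keep_mrnas:
            sub.graph.add_node(m, bipartite=0)
            sub.graph.add_node(g, bipartite=1)
            sub.graph.add_edge(m, g, **network.graph.edges[m, g])
    return sub
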