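"""Mean-threshold edge retention and the bipartite gene ↔ stress-unit network.

Edge candidates are (gene, subunit member, stress) records weighted by their
Pearson score. Retention keeps the records whose score is greater than or
equal to the mean of the subunit's score distribution (ties at the mean are
kept). The surviving records define a bipartite graph: gene nodes on one
side, stress-unit nodes (one per (stress, member) pair, the SU_{i,j} of the
network model) on the other, one weighted edge per surviving record. Nodes
with no surviving edge are absent, so with full coverage the stress-unit
side has exactly |stresses| x |members| nodes (35 / 70 / 14 for the default
A / B / C subunit layouts).

The threshold is applied to raw signed scores by default: an above-mean rule
on signed Pearson values effectively discards negative correlations, which is
the intended reading. An ``absolute`` flag is available for sensitivity
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import networkx as nx
import numpy as np

from .config_io import (
    CoexpressionTable,
    StressSet,
    SubunitConfig,
    ValidationError,
)

__all__ = [
    "ThresholdReport",
    "SUNode",
    "BipartiteNetwork",
    "compute_threshold",
    "apply_threshold",
    "build_bipartite_network",
    "export_gexf",
    "load_gexf",
]


class SUNode(NamedTuple):
    """A stress-unit node: identity is the (stress, member) pair."""

    stress: str
    member: str


@dataclass
class ThresholdReport:
    """Result of the mean-threshold computation for one subunit.

    ``mean_score`` is the pooled mean over every record of the subunit; in
    ``per_stress`` mode the applicable cutoff for a record is the mean of its
    own stress, held in ``per_stress_means``.
    """

    subunit: str
    mean_score: float
    n_before: int
    n_after: int
    mode: str = "pooled"
    per_stress_means: Optional[dict[str, float]] = None
    absolute: bool = False

    def cutoff_for(self, stress: str) -> float:
        if self.mode == "per_stress":
            assert self.per_stress_means is not None
            return self.per_stress_means[stress]
        return self.mean_score


def _effective(score: float, absolute: bool) -> float:
    return abs(score) if absolute else score


def compute_threshold(
    table: CoexpressionTable,
    subunit: str,
    mode: str = "pooled",
    absolute: bool = False,
) -> ThresholdReport:
    """Mean score of a subunit's distribution and the resulting retention.

    ``pooled`` takes one mean over all of the subunit's records (the default:
    the per-stress networks are merged into one per-subunit network, so one
    distribution backs the cutoff); ``per_stress`` computes one mean per
    stress for sensitivity analysis.
    """
    if mode not in ("pooled", "per_stress"):
        raise ValidationError(f"unknown threshold mode {mode!r}")
    sub = table.for_subunit(subunit)
    if len(sub) == 0:
        raise ValidationError(f"no records for subunit {subunit!r}")
    values = np.array([_effective(r.score, absolute) for r in sub])
    pooled_mean = float(np.mean(values))
    per_stress: Optional[dict[str, float]] = None
    if mode == "per_stress":
        per_stress = {}
        for stress in {r.stress for r in sub}:
            sv = [_effective(r.score, absolute) for r in sub if r.stress == stress]
            per_stress[stress] = float(np.mean(sv))
    report = ThresholdReport(
        subunit=subunit,
        mean_score=pooled_mean,
        n_before=len(sub),
        n_after=0,
        mode=mode,
        per_stress_means=per_stress,
        absolute=absolute,
    )
    report.n_after = sum(
        1
        for r in sub
        if _effective(r.score, absolute) >= report.cutoff_for(r.stress)
    )
    return report


def apply_threshold(
    table: CoexpressionTable, report: ThresholdReport
) -> CoexpressionTable:
    """Keep exactly the subunit's records at or above the applicable mean.

    Record order is preserved. The result contains only records of the
    report's subunit.
    """
    survivors = [
        r
        for r in table.for_subunit(report.subunit)
        if _effective(r.score, report.absolute) >= report.cutoff_for(r.stress)
    ]
    return CoexpressionTable(survivors, provenance=table.provenance)


@dataclass
class BipartiteNetwork:
    """Gene nodes, stress-unit nodes, and one weighted edge per record.

    Only gene ↔ stress-unit edges exist (genes are never joined directly),
    and every node carries at least one edge; thresholding happens upstream,
    so a node that lost all its records simply never appears.
    """

    subunit: str
    gene_nodes: set[str] = field(default_factory=set)
    su_nodes: set[SUNode] = field(default_factory=set)
    edges: list[tuple[str, SUNode, float]] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.gene_nodes) + len(self.su_nodes)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene in self.gene_nodes:
            g.add_node(gene, kind="gene")
        for su in self.su_nodes:
            g.add_node(su, kind="stress_unit")
        for gene, su, weight in self.edges:
            g.add_edge(gene, su, weight=weight)
        return g

    def adjacency(self) -> dict:
        """Node -> set of neighbours, over gene ids and SUNode keys."""
        adj: dict = {n: set() for n in self.gene_nodes}
        adj.update({n: set() for n in self.su_nodes})
        for gene, su, _ in self.edges:
            adj[gene].add(su)
            adj[su].add(gene)
        return adj


def build_bipartite_network(
    filtered: CoexpressionTable,
    subunit: str,
    stresses: StressSet,
    config: SubunitConfig,
) -> BipartiteNetwork:
    """Assemble the bipartite network from threshold survivors.

    Each surviving record contributes its gene node, its (stress, member)
    stress-unit node, and one edge weighted by the co-expression score. An
    empty input yields an empty network.
    """
    members = set(config.members(subunit))
    net = BipartiteNetwork(subunit=subunit)
    for r in filtered:
        if r.subunit != subunit:
            raise ValidationError(
                f"record for subunit {r.subunit!r} passed to {subunit!r} network"
            )
        if r.stress not in stresses or r.member not in members:
            raise ValidationError(f"record {r[:4]} inconsistent with configuration")
        su = SUNode(r.stress, r.member)
        net.gene_nodes.add(r.gene_id)
        net.su_nodes.add(su)
        net.edges.append((r.gene_id, su, r.score))
    return net


_SU_PREFIX = "SU|"


def export_gexf(network: BipartiteNetwork, path: str | Path) -> None:
    """Write the network as GEXF with a node ``kind`` attribute.

    Stress-unit node ids are serialised as ``SU|<stress>|<member>``; edge
    weights are rounded to 6 decimal places (the round-trip precision
    contract of this exporter).
    """
    g = nx.Graph()
    for gene in sorted(network.gene_nodes):
        g.add_node(gene, kind="gene")
    for su in sorted(network.su_nodes):
        g.add_node(f"{_SU_PREFIX}{su.stress}|{su.member}", kind="stress_unit")
    for gene, su, weight in network.edges:
        g.add_edge(gene, f"{_SU_PREFIX}{su.stress}|{su.member}", weight=round(weight, 6))
    nx.write_gexf(g, str(path))


def load_gexf(path: str | Path, subunit: str = "") -> BipartiteNetwork:
    """Re-import a network written by :func:`export_gexf`."""
    g = nx.read_gexf(str(path))
    net = BipartiteNetwork(subunit=subunit)
    for node, data in g.nodes(data=True):
        if data.get("kind") == "stress_unit":
            _, stress, member = node.split("|")
            net.su_nodes.add(SUNode(stress, member))
        else:
            net.gene_nodes.add(node)
    for u, v, data in g.edges(data=True):
        if u.startswith(_SU_PREFIX):
            u, v = v, u
        _, stress, member = v.split("|")
        net.edges.append((u, SUNode(stress, member), float(data["weight"])))
    return net
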