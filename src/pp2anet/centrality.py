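"""Closeness-centrality scoring, high-CCS selection, and hub intersection.

The closeness centrality of a node x is C_x = n / sum_y d(x, y), where the
sum runs over the nodes reachable from x and d is the unweighted
shortest-path hop count. Two readings of the normalising n are offered:

* ``reachable_count`` (default): n is the number of nodes reachable from x,
  excluding x itself. Scores then lie in (0, 1] for nodes in non-singleton
  components, and a star centre scores exactly 1.
* ``classic_n``: the reachable-count score is additionally multiplied by the
  Wasserman-Faust component factor (reachable / (N - 1) with N the node count
  of the whole graph), which penalises small components.

Distances never cross connected components; isolated nodes score 0.

Hub genes are genes selected as high-CCS in every subunit network: each
subunit's gene scores are cut either at an absolute threshold or at the
largest consecutive drop in the sorted unique score values ("largest gap"),
and the per-subunit selections are intersected.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Hashable, Optional, Sequence

from .config_io import ValidationError
from .network import BipartiteNetwork

__all__ = [
    "CentralityTable",
    "HubSelection",
    "HubIntersection",
    "closeness_centrality",
    "select_high_ccs",
    "intersect_hubs",
]


@dataclass
class CentralityTable:
    """Node -> closeness score, under a stated normalisation convention."""

    scores: dict[Hashable, float]
    convention: str = "reachable_count"

    def restrict(self, nodes) -> "CentralityTable":
        keep = set(nodes)
        return CentralityTable(
            {n: s for n, s in self.scores.items() if n in keep},
            convention=self.convention,
        )

    def gene_scores(self, network: BipartiteNetwork) -> "CentralityTable":
        return self.restrict(network.gene_nodes)


def _bfs_distances(adj: dict, source: Hashable) -> dict[Hashable, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    del dist[source]
    return dist


def closeness_centrality(
    network: BipartiteNetwork, convention: str = "reachable_count"
) -> CentralityTable:
    """Score every node of the network by closeness (hop-count distances)."""
    if convention not in ("reachable_count", "classic_n"):
        raise ValidationError(f"unknown convention {convention!r}")
    adj = network.adjacency()
    total = len(adj)
    scores: dict[Hashable, float] = {}
    for node in adj:
        dist = _bfs_distances(adj, node)
        if not dist:
            scores[node] = 0.0
            continue
        reachable = len(dist)
        c = reachable / sum(dist.values())
        if convention == "classic_n" and total > 1:
            c *= reachable / (total - 1)
        scores[node] = c
    return CentralityTable(scores, convention=convention)


@dataclass
class HubSelection:
    """Genes whose closeness survives the per-subunit cutoff."""

    subunit: str
    selected: frozenset[str]
    cutoff: float
    method: str


def select_high_ccs(
    table: CentralityTable,
    method: str = "largest_gap",
    threshold: Optional[float] = None,
    subunit: str = "",
) -> HubSelection:
    """Select high-closeness genes.

    ``largest_gap`` sorts the *unique* score values descending and cuts at
    the largest consecutive difference (so heavy ties do not fragment the gap
    structure); everything at or above the cut survives. When several gaps
    tie for largest, the highest one is used — the conservative, smallest
    selection. With a single unique value every gene is selected.

    ``absolute`` keeps genes scoring at or above ``threshold`` (inclusive).
    """
    if not table.scores:
        return HubSelection(subunit, frozenset(), float("nan"), method)
    if method == "absolute":
        if threshold is None:
            raise ValidationError("absolute selection requires a threshold")
        cutoff = threshold
    elif method == "largest_gap":
        unique = sorted(set(table.scores.values()), reverse=True)
        if len(unique) == 1:
            cutoff = unique[0]
        else:
            gaps = [unique[i] - unique[i + 1] for i in range(len(unique) - 1)]
            cut_index = gaps.index(max(gaps))
            cutoff = unique[cut_index]
    else:
        raise ValidationError(f"unknown selection method {method!r}")
    selected = frozenset(g for g, s in table.scores.items() if s >= cutoff)
    return HubSelection(subunit, selected, cutoff, method)


@dataclass
class HubIntersection:
    """Genes high-CCS in every contributing subunit."""

    hubs: frozenset[str]
    per_subunit: list[HubSelection] = field(default_factory=list)


def intersect_hubs(selections: Sequence[HubSelection]) -> HubIntersection:
    """Intersect per-subunit selections; an empty intersection is valid."""
    if len(selections) < 2:
        raise ValidationError("need at least two selections to intersect")
    hubs = frozenset(
        set.intersection(*(set(sel.selected) for sel in selections))
    )
    return HubIntersection(hubs=hubs, per_subunit=list(selections))
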