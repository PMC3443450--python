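"""Co-segregation groups from the two-point linkage graph.

Markers become nodes; an edge joins an informative pair whose LOD reaches
``lod_min`` and whose estimated recombination fraction does not exceed
``rf_max`` (map defaults: LOD >= 6, rf <= 0.35).  Connected components are
the co-segregation groups — the polyploid analogue of linkage groups, one
per homolog.  D1 x D2 pairs can never contribute edges: their linkage is
invisible to two-point analysis, and D1 and D2 markers end up in one group
only when 3:1 C markers bridge them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .twopoint import PairEstimate

DEFAULT_LOD_MIN = 6.0
DEFAULT_RF_MAX = 0.35


@dataclass
class CoSegregationGroup:
    name: str
    markers: list[str]

    @property
    def size_markers(self) -> int:
        return len(self.markers)


@dataclass
class GroupingResult:
    groups: list[CoSegregationGroup]
    unlinked: list[str]
    graph: nx.Graph = field(repr=False, default=None)


def build_linkage_graph(
    estimates: list[PairEstimate],
    lod_min: float = DEFAULT_LOD_MIN,
    rf_max: float = DEFAULT_RF_MAX,
    markers: list[str] | None = None,
) -> nx.Graph:
    """Undirected graph with an edge per pair passing both thresholds."""
    g = nx.Graph()
    if markers is not None:
        g.add_nodes_from(markers)
    for est in estimates:
        g.add_node(est.marker_a)
        g.add_node(est.marker_b)
        if not est.informative:
            continue
        if est.lod >= lod_min and est.rf_hat <= rf_max:
            g.add_edge(est.marker_a, est.marker_b, lod=est.lod, rf=est.rf_hat)
    return g


def co_segregation_groups(graph: nx.Graph) -> GroupingResult:
    """Connected components, deterministically named and ordered.

    Components sort by marker count descending, then by their
    lexicographically smallest member, so the partition (and naming) does
    not depend on marker input order.  Markers in no edge are unlinked.
    """
    comps = [sorted(c) for c in nx.connected_components(graph)]
    linked = [c for c in comps if len(c) > 1]
    unlinked = sorted(m for c in comps if len(c) == 1 for m in c)
    linked.sort(key=lambda c: (-len(c), c[0]))
    groups = [
        CoSegregationGroup(name=f"CG{i + 1:03d}", markers=c)
        for i, c in enumerate(linked)
    ]
    return GroupingResult(groups=groups, unlinked=unlinked, graph=graph)
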