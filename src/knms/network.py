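"""Component-target network construction and topology statistics."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx

from .types import Component, CTNetwork, CT_EDGE, TT_EDGE

__all__ = ["NetworkStats", "build_network", "network_stats", "connected_components"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkStats:
    """Degree statistics of a component-target network.

    The mean component/target degrees are computed over component-target
    edges only (``mean_target_degree_ct``) and over all edges including
    target-target interactions (``mean_target_degree_all``); both are
    reported because they differ as soon as interaction edges are merged in.
    """

    n_components: int
    n_targets: int
    n_edges: int
    n_ct_edges: int
    mean_component_degree: Optional[float]
    mean_target_degree_ct: Optional[float]
    mean_target_degree_all: Optional[float]
    degree: dict[str, int]


def build_network(components: Sequence[Component] | Sequence[str],
                  ct_edges: Sequence[tuple],
                  tti_edges: Optional[Sequence[tuple]] = None) -> CTNetwork:
    """Assemble the bipartite C-T graph, optionally merged with TTI edges.

    ``components`` may be :class:`Component` records or bare id strings.
    Every component-target edge must reference a known component id; target
    nodes are created on first sight (gene symbols upper-cased).  TTI edges
    may introduce new target nodes.  Components left with degree 0 are
    retained but flagged with a warning.
    """
    net = CTNetwork()
    ids = []
    for c in components:
        cid = c.id if isinstance(c, Component) else str(c)
        ids.append(cid)
        net.add_component(cid)
    known = set(ids)

    unknown = sorted({u for u, v, *_ in ct_edges if u not in known})
    if unknown:
        raise ValueError(f"component-target edges reference unknown component ids: {unknown}")
    for u, v, *rest in ct_edges:
        w = float(rest[0]) if rest else 1.0
        net.add_target(v.upper())
        net.add_edge(u, v.upper(), kind=CT_EDGE, weight=w)
    for edge in tti_edges or []:
        u, v, *rest = edge
        w = float(rest[0]) if rest else 1.0
        u, v = u.upper(), v.upper()
        net.add_target(u)
        net.add_target(v)
        net.add_edge(u, v, kind=TT_EDGE, weight=w)

    isolated = sorted(n for n in net.component_nodes if net.graph.degree(n) == 0)
    if isolated:
        log.warning("isolated components (degree 0) retained: %s", isolated)
    return net


def network_stats(net: CTNetwork) -> NetworkStats:
    """Degree statistics; means to two decimals, C-T-only and all-edge views."""
    comps = net.component_nodes
    targets = net.target_nodes
    if not comps and not targets:
        raise ValueError("empty network")
    ct_edges = list(net.edges(kind=CT_EDGE))
    n_ct = len(ct_edges)
    n_edges = net.graph.number_of_edges()
    degree = {n: net.graph.degree(n) for n in net.graph.nodes}

    def mean2(num: float, den: int) -> Optional[float]:
        return round(num / den, 2) if den else None

    # component degrees touch only C-T edges, so the all-edge view is identical
    mean_comp = mean2(n_ct, len(comps))
    mean_t_ct = mean2(n_ct, len(targets))
    all_target_deg = sum(degree[t] for t in targets)
    mean_t_all = mean2(all_target_deg, len(targets))
    return NetworkStats(
        n_components=len(comps),
        n_targets=len(targets),
        n_edges=n_edges,
        n_ct_edges=n_ct,
        mean_component_degree=mean_comp,
        mean_target_degree_ct=mean_t_ct,
        mean_target_degree_all=mean_t_all,
        degree=degree,
    )


def connected_components(net: CTNetwork) -> list[set[str]]:
    """Connected components, largest first; ties by smallest member node id."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
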