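"""Domain types shared across the pipeline.

The pipeline studies multi-herb prescriptions (formulas) whose chemical
components act on protein targets.  A :class:`Component` is one screened
molecule with its ADME properties; a :class:`CTNetwork` is the bipartite
component-target graph (optionally augmented with target-target interaction
edges); a :class:`Partition` assigns every network node to exactly one
module, the unit on which codelength and significance are computed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

__all__ = [
    "Component",
    "CTNetwork",
    "DiseaseGeneList",
    "PathwayCollection",
    "Partition",
    "normalize_name",
]

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold a component name and collapse internal whitespace.

    Component identity across formulas is by normalized name: the same
    molecule appears under different herbs and formula-local ids, so set
    operations (common/unique accounting) must key on the name.
    """
    return _WS.sub(" ", name.strip()).casefold()


@dataclass(frozen=True)
class Component:
    """One screened molecule with its ADME property profile.

    Properties are inputs (from upstream databases), never computed here.
    ``ob`` is oral bioavailability in percent; ``dl`` is the unitless
    drug-likeness score in [0, 1]; ``hdon``/``hacc``/``rbn`` are hydrogen
    bond donor/acceptor and rotatable bond counts.
    """

    id: str
    name: str
    formula: str
    herb: str
    mw: float
    logp: float
    hdon: int
    hacc: int
    rbn: int
    ob: float
    dl: float
    smiles: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mw > 0:
            raise ValueError(f"{self.id}: mw must be positive, got {self.mw}")
        for attr in ("hdon", "hacc", "rbn"):
            v = getattr(self, attr)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{self.id}: {attr} must be a non-negative integer, got {v!r}")
        if self.ob < 0:
            raise ValueError(f"{self.id}: ob must be >= 0, got {self.ob}")
        if not 0.0 <= self.dl <= 1.0:
            raise ValueError(f"{self.id}: dl must be in [0, 1], got {self.dl}")

    @property
    def norm_name(self) -> str:
        return normalize_name(self.name)


COMPONENT = "component"
TARGET = "target"
CT_EDGE = "component-target"
TT_EDGE = "target-target"


class CTNetwork:
    """Bipartite component-target network, optionally with target-target edges.

    Thin wrapper over an undirected :class:`networkx.Graph`.  Nodes carry a
    ``kind`` attribute (``component`` or ``target``); edges carry ``kind``
    (``component-target`` or ``target-target``) and a positive ``weight``
    (default 1).  Component-component edges and self-loops are forbidden;
    component ids and gene symbols live in disjoint namespaces.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()

    # -- construction ------------------------------------------------------

    def add_component(self, node: str) -> None:
        if node in self.graph and self.graph.nodes[node]["kind"] != COMPONENT:
            raise ValueError(f"node id {node!r} already used as a target")
        self.graph.add_node(node, kind=COMPONENT)

    def add_target(self, node: str) -> None:
        if node in self.graph and self.graph.nodes[node]["kind"] != TARGET:
            raise ValueError(f"node id {node!r} already used as a component")
        self.graph.add_node(node, kind=TARGET)

    def add_edge(self, u: str, v: str, kind: str, weight: float = 1.0) -> None:
        if u == v:
            raise ValueError(f"self-loop {u!r} forbidden")
        if weight <= 0:
            raise ValueError(f"edge weight must be positive, got {weight}")
        if kind not in (CT_EDGE, TT_EDGE):
            raise ValueError(f"unknown edge kind {kind!r}")
        ku = self.graph.nodes[u]["kind"]
        kv = self.graph.nodes[v]["kind"]
        if ku == COMPONENT and kv == COMPONENT:
            raise ValueError(f"component-component edge {u!r}-{v!r} forbidden")
        expected = CT_EDGE if COMPONENT in (ku, kv) else TT_EDGE
        if kind != expected:
            raise ValueError(f"edge {u!r}-{v!r} joins {ku}/{kv}; kind must be {expected!r}")
        self.graph.add_edge(u, v, kind=kind, weight=float(weight))

    # -- views -------------------------------------------------------------

    @property
    def component_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == COMPONENT}

    @property
    def target_nodes(self) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == TARGET}

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self, kind: Optional[str] = None):
        for u, v, d in self.graph.edges(data=True):
            if kind is None or d["kind"] == kind:
                yield u, v, d

    def weighted_degree(self, node: str) -> float:
        return self.graph.degree(node, weight="weight")

    def total_weight(self) -> float:
        return self.graph.size(weight="weight")

    def subgraph(self, nodes: Iterable[str]) -> "CTNetwork":
        sub = CTNetwork()
        sub.graph = self.graph.subgraph(nodes).copy()
        return sub

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class DiseaseGeneList:
    """Disease (pathogenic) genes with literature-evidence counts."""

    records: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        cleaned = []
        for symbol, count in self.records:
            sym = symbol.strip().upper()
            if count < 0:
                raise ValueError(f"{sym}: evidence_count must be >= 0, got {count}")
            if sym in seen:
                raise ValueError(f"duplicate gene symbol {sym!r} after case normalization")
            seen[sym] = count
            cleaned.append((sym, int(count)))
        self.records = cleaned

    def symbols(self) -> set[str]:
        return {s for s, _ in self.records}


@dataclass
class PathwayCollection:
    """Mapping pathway id -> (description, gene symbol set)."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, (_, genes) in self.pathways.items():
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways)

    def genes(self, pid: str) -> frozenset[str]:
        return self.pathways[pid][1]

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, genes in self.pathways.values():
            out |= genes
        return out


class Partition:
    """Assignment of every network node to exactly one module.

    Module ids are dense integers starting at 1.  Construction renumbers
    arbitrary labels into that canonical form, ordering modules by their
    smallest member node id for determinism.
    """

    def __init__(self, assignment: Mapping[str, object]) -> None:
        if not assignment:
            raise ValueError("empty partition")
        groups: dict[object, list[str]] = {}
        for node, label in assignment.items():
            groups.setdefault(label, []).append(node)
        ordered = sorted(groups.values(), key=lambda members: min(members))
        self._assignment: dict[str, int] = {}
        self._members: dict[int, frozenset[str]] = {}
        for mid, members in enumerate(ordered, start=1):
            self._members[mid] = frozenset(members)
            for node in members:
                self._assignment[node] = mid

    @classmethod
    def singletons(cls, nodes: Iterable[str]) -> "Partition":
        return cls({n: n for n in nodes})

    @classmethod
    def one_module(cls, nodes: Iterable[str]) -> "Partition":
        return cls({n: 1 for n in nodes})

    def module_of(self, node: str) -> int:
        return self._assignment[node]

    @property
    def assignment(self) -> dict[str, int]:
        return dict(self._assignment)

    @property
    def members(self) -> dict[int, frozenset[str]]:
        return dict(self._members)

    @property
    def module_ids(self) -> list[int]:
        return sorted(self._members)

    @property
    def n_modules(self) -> int:
        return len(self._members)

    def nodes(self) -> set[str]:
        return set(self._assignment)

    def __len__(self) -> int:
        return len(self._assignment)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return set(self._members.values()) == set(other._members.values())

    def __hash__(self) -> int:
        return hash(frozenset(self._members.values()))

    def __repr__(self) -> str:
        return f"Partition({self.n_modules} modules, {len(self)} nodes)"
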