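"""Seeded generators for every input the pipeline consumes.

Includes the packaged 292-row screened component table (the three studied
prescriptions with their published ADME property profiles) and synthetic
generators: bipartite planted-partition networks with known module
structure, pathway collections with controllable enrichment signal, disease
gene lists, and property tables with a controllable pass/fail mix around
the screening thresholds.  All generators are pure functions of their
seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np

from .adme import ScreenCriteria
from .io import read_component_table
from .network import build_network, connected_components
from .types import Component, CTNetwork, DiseaseGeneList, Partition, PathwayCollection

__all__ = [
    "packaged_table2",
    "PlantedNetworkSpec",
    "gen_planted_network",
    "gen_annotations",
    "gen_component_table",
]

log = logging.getLogger(__name__)


def packaged_table2() -> list[Component]:
    """The packaged post-screening component table (292 rows: 124+120+48)."""
    with resources.as_file(resources.files("knms").joinpath("data/table2.tsv")) as path:
        return read_component_table(path)


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Parameters of a bipartite planted-partition component-target network.

    Components and targets are split evenly into ``n_modules`` blocks; a
    component-target pair is linked with probability ``p_in`` inside a block
    and ``p_out`` across blocks.
    """

    n_components: int = 40
    n_targets: int = 80
    n_modules: int = 4
    p_in: float = 0.4
    p_out: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_modules > min(self.n_components, self.n_targets):
            raise ValueError("n_modules exceeds the smaller node set")


def gen_planted_network(spec: PlantedNetworkSpec) -> tuple[CTNetwork, Partition]:
    """Draw a planted bipartite network and its ground-truth partition.

    Redraws (up to 50 times) until the graph is connected; with ``p_out = 0``
    connectivity across blocks is impossible, so the last draw is returned
    with a warning instead.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    comp_ids = [f"C{i:03d}" for i in range(spec.n_components)]
    target_ids = [f"T{i:03d}" for i in range(spec.n_targets)]
    comp_block = {c: i % spec.n_modules for i, c in enumerate(comp_ids)}
    target_block = {t: i % spec.n_modules for i, t in enumerate(target_ids)}
    truth = Partition({**{c: comp_block[c] for c in comp_ids},
                       **{t: target_block[t] for t in target_ids}})

    expected_deg = spec.p_in * spec.n_targets / spec.n_modules
    if expected_deg < 1:
        log.warning("expected within-block component degree %.2f < 1; "
                    "connectivity not guaranteed", expected_deg)

    for attempt in range(50):
        edges = []
        for c in comp_ids:
            probs = np.where(
                np.array([target_block[t] for t in target_ids]) == comp_block[c],
                spec.p_in, spec.p_out)
            hits = rng.random(spec.n_targets) < probs
            edges.extend((c, t) for t, hit in zip(target_ids, hits) if hit)
        net = build_network(comp_ids, edges)
        live = [n for n in net.graph.nodes if net.graph.degree(n) > 0]
        sub = net.subgraph(live)
        if len(live) == len(net.graph.nodes) and len(connected_components(sub)) == 1:
            return net, truth
        if spec.p_out == 0.0 and attempt == 0:
            log.warning("p_out = 0: graph cannot connect across blocks; "
                        "returning the first draw")
            return net, truth
    log.warning("no connected draw in 50 attempts; returning the last one")
    return net, truth


def gen_annotations(network: CTNetwork, n_pathways: int = 20,
                    n_disease: int = 15, signal: float = 0.8,
                    seed: Optional[int] = None,
                    truth: Optional[Partition] = None,
                    ) -> tuple[PathwayCollection, DiseaseGeneList]:
    """Sample a pathway collection and a disease gene list for a network.

    Each pathway draws 10-30 target genes; with probability ``signal`` a
    pathway is anchored to one planted block (80% of its genes from that
    block), otherwise genes are sampled uniformly, so ``signal = 0`` makes
    pathway membership independent of module structure.  Disease genes get
    literature-evidence counts uniform on 1..20.
    """
    targets = sorted(network.target_nodes)
    if not targets:
        raise ValueError("network has no targets")
    if n_disease > len(targets):
        raise ValueError(f"n_disease = {n_disease} exceeds {len(targets)} targets")
    if not 0.0 <= signal <= 1.0:
        raise ValueError("signal must be in [0, 1]")
    rng = np.random.default_rng(seed)

    blocks: dict[int, list[str]] = {}
    if truth is not None:
        for t in targets:
            blocks.setdefault(truth.module_of(t), []).append(t)

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    for i in range(n_pathways):
        size = int(rng.integers(10, 31))
        size = min(size, len(targets))
        if blocks and rng.random() < signal:
            block = blocks[rng.choice(sorted(blocks))]
            n_core = min(len(block), max(1, int(round(0.8 * size))))
            core = rng.choice(block, size=n_core, replace=False).tolist()
            rest_pool = [t for t in targets if t not in set(core)]
            n_rest = min(size - n_core, len(rest_pool))
            rest = rng.choice(rest_pool, size=n_rest, replace=False).tolist() if n_rest else []
            genes = frozenset(core + rest)
        else:
            genes = frozenset(rng.choice(targets, size=size, replace=False).tolist())
        pathways[f"PW{i + 1:03d}"] = (f"synthetic pathway {i + 1}", genes)

    disease_syms = rng.choice(targets, size=n_disease, replace=False).tolist()
    records = [(s, int(rng.integers(1, 21))) for s in disease_syms]
    return PathwayCollection(pathways), DiseaseGeneList(records)


def gen_component_table(n_pass: int = 20, n_fail: int = 10,
                        formula: str = "SYN", seed: Optional[int] = None,
                        criteria: ScreenCriteria = ScreenCriteria(),
                        ) -> list[Component]:
    """Property table with a controllable pass/fail mix around the thresholds.

    Passing rows sample every property inside the screening bounds; failing
    rows violate one randomly chosen rule (placed just beyond its bound, so
    the table exercises the threshold edges).
    """
    rng = np.random.default_rng(seed)
    rows: list[Component] = []

    def draw_passing(i: int, herb: str) -> dict:
        return dict(
            id=f"{formula}{i}", name=f"compound-{i}", formula=formula, herb=herb,
            mw=float(round(rng.uniform(150, criteria.mw_max), 2)),
            logp=float(round(rng.uniform(criteria.logp_min, criteria.logp_max), 2)),
            hdon=int(rng.integers(0, criteria.hdon_max + 1)),
            hacc=int(rng.integers(0, criteria.hacc_max + 1)),
            rbn=int(rng.integers(0, criteria.rbn_max + 1)),
            ob=float(round(rng.uniform(criteria.ob_min, 110), 2)),
            dl=float(round(rng.uniform(criteria.dl_min, 1.0), 2)),
        )

    rules = ["mw", "hdon", "hacc", "logp", "rbn", "ob", "dl"]
    for i in range(n_pass):
        rows.append(Component(**draw_passing(i + 1, herb="herbA")))
    for j in range(n_fail):
        kw = draw_passing(n_pass + j + 1, herb="herbB")
        rule = rules[int(rng.integers(0, len(rules)))]
        if rule == "mw":
            kw["mw"] = criteria.mw_max + float(round(rng.uniform(1, 200), 2))
        elif rule == "hdon":
            kw["hdon"] = criteria.hdon_max + int(rng.integers(1, 4))
        elif rule == "hacc":
            kw["hacc"] = criteria.hacc_max + int(rng.integers(1, 4))
        elif rule == "logp":
            kw["logp"] = criteria.logp_max + float(round(rng.uniform(0.1, 3), 2))
        elif rule == "rbn":
            kw["rbn"] = criteria.rbn_max + int(rng.integers(1, 5))
        elif rule == "ob":
            kw["ob"] = float(round(rng.uniform(0, criteria.ob_min - 0.1), 2))
        else:
            kw["dl"] = float(round(rng.uniform(0, criteria.dl_min - 0.01), 2))
        rows.append(Component(**kw))
    return rows
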