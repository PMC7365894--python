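from __future__ import annotations

import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from knms.types import Component, CTNetwork


def tt_graph(edges, weights=None) -> CTNetwork:
    """Build a network of target-target edges (unipartite view for walk tests)."""
    net = CTNetwork()
    nodes = sorted({x for e in edges for x in e})
    for n in nodes:
        net.add_target(n)
    for i, (u, v) in enumerate(edges):
        w = 1.0 if weights is None else weights[i]
        net.add_edge(u, v, kind="target-target", weight=w)
    return net


def random_connected_net(rng: np.random.Generator, n_min=3, n_max=8) -> CTNetwork:
    """A small random connected graph as a CTNetwork (resampled until connected)."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
        if g.number_of_edges() and nx.is_connected(g):
            return tt_graph([(f"n{u}", f"n{v}") for u, v in g.edges])


def make_component(**overrides) -> Component:
    base = dict(id="X1", name="compound-x", formula="DSD", herb="herbA",
                mw=300.0, logp=2.0, hdon=2, hacc=4, rbn=3, ob=50.0, dl=0.3)
    base.update(overrides)
    return Component(**base)


@pytest.fixture(scope="session")
def table2():
    from knms.fixtures import packaged_table2
    return packaged_table2()
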