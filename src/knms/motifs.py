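"""Map-equation module detection on component-target networks.

A random walker on the undirected network visits node ``a`` with stationary
probability ``p_a = w_a / 2W`` (weighted degree over twice the total edge
weight).  For a partition M of the n nodes into m modules, the two-level map
equation gives the expected per-step description length in bits::

    L(M) = q_enter * H(Q) + sum_i p_circ_i * H(P_i)

where ``q_i = w_boundary(i) / 2W`` is the rate at which the walker enters
(equivalently, for undirected walks, exits) module i, ``q_enter`` their sum,
``p_circ_i = q_i + sum_{a in i} p_a`` the use rate of module i's codebook,
and H the Shannon entropy of the normalized rate distributions.  Minimizing
L(M) finds the modules ("key gene network motifs"); their statistical
significance is then assessed against a degree-preserving rewiring null.

All logarithms are base 2 and ``0 * log 0 := 0``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from .network import connected_components
from .types import CTNetwork, Partition

__all__ = [
    "CodelengthTerms",
    "MotifResult",
    "visit_rates",
    "codelength",
    "optimize_partition",
    "brute_force_partition",
    "module_significance",
    "detect_motifs",
]


def _plogp(x: float) -> float:
    return x * math.log2(x) if x > 0.0 else 0.0


@dataclass(frozen=True)
class CodelengthTerms:
    """Every symbol of the map equation for one partition."""

    p_alpha: dict[str, float]
    q_enter_i: dict[int, float]
    q_exit_i: dict[int, float]
    q_enter_total: float
    p_circ_i: dict[int, float]
    h_index: float
    h_module_i: dict[int, float]
    codelength: float
    m: int
    n: int


@dataclass
class MotifResult:
    """Best partition found plus (optionally) per-module significance."""

    partition: Partition
    terms: CodelengthTerms
    p_values: dict[int, float] = field(default_factory=dict)
    q_values: dict[int, float] = field(default_factory=dict)
    knms: set[int] = field(default_factory=set)
    trials: int = 0
    seed: Optional[int] = None


def visit_rates(net: CTNetwork) -> dict[str, float]:
    """Stationary visit probability of each node: weighted degree over 2W.

    Nodes with degree 0 cannot be visited by the walk; callers must drop
    them upstream (an error is raised here).
    """
    if len(net) == 0:
        raise ValueError("empty network")
    total = net.total_weight()
    if total <= 0:
        raise ValueError("network has no edges")
    rates = {}
    for node in net.graph.nodes:
        w = net.weighted_degree(node)
        if w == 0:
            raise ValueError(f"node {node!r} is isolated; drop isolated nodes before the walk")
        rates[node] = w / (2.0 * total)
    return rates


def codelength(net: CTNetwork, partition: Partition) -> CodelengthTerms:
    """Evaluate the map equation term by term for a given partition."""
    if partition.nodes() != set(net.graph.nodes):
        missing = set(net.graph.nodes) - partition.nodes()
        extra = partition.nodes() - set(net.graph.nodes)
        raise ValueError(f"partition does not cover the graph (missing={sorted(missing)}, "
                         f"extra={sorted(extra)})")
    p = visit_rates(net)
    total = net.total_weight()

    boundary: dict[int, float] = {mid: 0.0 for mid in partition.module_ids}
    for u, v, d in net.graph.edges(data=True):
        mu, mv = partition.module_of(u), partition.module_of(v)
        if mu != mv:
            boundary[mu] += d["weight"]
            boundary[mv] += d["weight"]
    q_exit = {mid: b / (2.0 * total) for mid, b in boundary.items()}
    q_enter = dict(q_exit)  # undirected walk: entry and exit rates coincide
    q_total = sum(q_enter.values())

    h_index = 0.0
    if q_total > 0:
        h_index = -sum(_plogp(q / q_total) for q in q_enter.values())

    p_circ: dict[int, float] = {}
    h_module: dict[int, float] = {}
    for mid, members in partition.members.items():
        s = sum(p[a] for a in members)
        circ = s + q_exit[mid]
        p_circ[mid] = circ
        h = 0.0
        if circ > 0:
            h = -_plogp(q_exit[mid] / circ) - sum(_plogp(p[a] / circ) for a in members)
        h_module[mid] = h

    L = q_total * h_index + sum(p_circ[mid] * h_module[mid] for mid in p_circ)
    return CodelengthTerms(
        p_alpha=p,
        q_enter_i=q_enter,
        q_exit_i=q_exit,
        q_enter_total=q_total,
        p_circ_i=p_circ,
        h_index=h_index,
        h_module_i=h_module,
        codelength=L,
        m=partition.n_modules,
        n=len(partition),
    )


# ---------------------------------------------------------------------------
# incremental optimizer state
#
# With g(x) = x log2 x, S_i the summed visit rates of module i and q_i its
# boundary rate, the map equation collapses to
#
#   L = g(Q) - 2 sum_i g(q_i) + sum_i g(q_i + S_i) - sum_a g(p_a),  Q = sum q_i
#
# which lets node moves be scored from per-module aggregates alone.
# ---------------------------------------------------------------------------


class _State:
    def __init__(self, net: CTNetwork, labels: dict[str, int]):
        self.p = visit_rates(net)
        self.total = net.total_weight()
        self.labels = dict(labels)
        # adjacency with weights normalized to rate units (w / 2W)
        self.adj: dict[str, list[tuple[str, float]]] = {n: [] for n in net.graph.nodes}
        for u, v, d in net.graph.edges(data=True):
            r = d["weight"] / (2.0 * self.total)
            self.adj[u].append((v, r))
            self.adj[v].append((u, r))
        self.sum_p: dict[int, float] = {}
        self.q: dict[int, float] = {}
        for n, lab in self.labels.items():
            self.sum_p[lab] = self.sum_p.get(lab, 0.0) + self.p[n]
            self.q.setdefault(lab, 0.0)
        for u in self.adj:
            lu = self.labels[u]
            for v, r in self.adj[u]:
                if self.labels[v] != lu:
                    self.q[lu] += r
        self.const = -sum(_plogp(x) for x in self.p.values())

    def clone(self) -> "_State":
        other = _State.__new__(_State)
        other.p = self.p
        other.total = self.total
        other.adj = self.adj
        other.const = self.const
        other.labels = dict(self.labels)
        other.sum_p = dict(self.sum_p)
        other.q = dict(self.q)
        return other

    def codelength(self) -> float:
        Q = sum(self.q.values())
        L = _plogp(Q) + self.const
        for lab in self.q:
            L -= 2.0 * _plogp(self.q[lab])
            L += _plogp(self.q[lab] + self.sum_p[lab])
        return L

    def _module_terms(self, q: float, s: float, Q_removed: float) -> float:
        # contribution of one module given the rest of Q
        return -2.0 * _plogp(q) + _plogp(q + s)

    def rates_to_modules(self, node: str) -> dict[int, float]:
        out: dict[int, float] = {}
        for v, r in self.adj[node]:
            lab = self.labels[v]
            out[lab] = out.get(lab, 0.0) + r
        return out

    def move_delta(self, node: str, new_lab: int,
                   to_mod: Optional[dict[int, float]] = None) -> float:
        """Change in L from moving ``node`` to module ``new_lab``."""
        old_lab = self.labels[node]
        if new_lab == old_lab:
            return 0.0
        to_mod = to_mod if to_mod is not None else self.rates_to_modules(node)
        p_node = self.p[node]
        deg_r = sum(r for _, r in self.adj[node])  # total rate mass at node
        w_old = to_mod.get(old_lab, 0.0)
        w_new = to_mod.get(new_lab, 0.0)

        q_old, s_old = self.q[old_lab], self.sum_p[old_lab]
        q_new = self.q.get(new_lab, 0.0)
        s_new = self.sum_p.get(new_lab, 0.0)

        # after the move: node's boundary contribution changes on both sides
        q_old2 = q_old - (deg_r - w_old) + w_old
        q_new2 = q_new + (deg_r - w_new) - w_new
        s_old2 = s_old - p_node
        s_new2 = s_new + p_node
        if s_old2 <= 1e-15 and q_old2 <= 1e-15:
            q_old2 = 0.0  # module emptied

        Q = sum(self.q.values())
        Q2 = Q - q_old - q_new + q_old2 + q_new2

        before = _plogp(Q) \
            - 2.0 * _plogp(q_old) + _plogp(q_old + s_old) \
            - 2.0 * _plogp(q_new) + _plogp(q_new + s_new)
        after = _plogp(Q2) \
            - 2.0 * _plogp(q_old2) + _plogp(q_old2 + s_old2) \
            - 2.0 * _plogp(q_new2) + _plogp(q_new2 + s_new2)
        return after - before

    def apply_move(self, node: str, new_lab: int) -> None:
        old_lab = self.labels[node]
        if new_lab == old_lab:
            return
        to_mod = self.rates_to_modules(node)
        p_node = self.p[node]
        deg_r = sum(r for _, r in self.adj[node])
        w_old = to_mod.get(old_lab, 0.0)
        w_new = to_mod.get(new_lab, 0.0)
        self.q[old_lab] = self.q[old_lab] - (deg_r - w_old) + w_old
        self.q[new_lab] = self.q.get(new_lab, 0.0) + (deg_r - w_new) - w_new
        self.sum_p[old_lab] -= p_node
        self.sum_p[new_lab] = self.sum_p.get(new_lab, 0.0) + p_node
        self.labels[node] = new_lab
        if self.sum_p[old_lab] <= 1e-15:
            del self.sum_p[old_lab]
            del self.q[old_lab]


_EPS = 1e-12


def _greedy_sweeps(state: _State, order: list[str]) -> None:
    """Move each node to the best neighboring module until no move helps."""
    improved = True
    while improved:
        improved = False
        for node in order:
            to_mod = state.rates_to_modules(node)
            current = state.labels[node]
            best_lab, best_delta = current, -_EPS
            # deterministic candidate order: smallest module label first
            for lab in sorted(to_mod):
                if lab == current:
                    continue
                delta = state.move_delta(node, lab, to_mod)
                if delta < best_delta - _EPS or (abs(delta - best_delta) <= _EPS
                                                 and lab < best_lab):
                    best_lab, best_delta = lab, delta
            if best_lab != current and best_delta < -_EPS:
                state.apply_move(node, best_lab)
                improved = True


def _merge_and_finetune(net: CTNetwork, state: _State, order: list[str]) -> _State:
    """Escape pairwise local optima: tentatively merge each connected module
    pair, re-run greedy sweeps on the merged labeling, and adopt the first
    merge whose combined effect lowers L.  Repeats until no merge helps."""
    improved = True
    while improved:
        improved = False
        pairs: set[tuple[int, int]] = set()
        for u, v, _ in net.graph.edges(data=True):
            lu, lv = state.labels[u], state.labels[v]
            if lu != lv:
                pairs.add((min(lu, lv), max(lu, lv)))
        base = state.codelength()
        for a, b in sorted(pairs):
            trial = state.clone()
            for n in [x for x, lab in trial.labels.items() if lab == b]:
                trial.apply_move(n, a)
            _greedy_sweeps(trial, order)
            if trial.codelength() < base - _EPS:
                state = trial
                improved = True
                break
    return state


def _labels_codelength(state: _State, labels: dict[str, int]) -> float:
    sum_p: dict[int, float] = {}
    q: dict[int, float] = {}
    for n, lab in labels.items():
        sum_p[lab] = sum_p.get(lab, 0.0) + state.p[n]
        q.setdefault(lab, 0.0)
    for u in state.adj:
        lu = labels[u]
        for v, r in state.adj[u]:
            if labels[v] != lu:
                q[lu] += r
    Q = sum(q.values())
    L = _plogp(Q) + state.const
    for lab in q:
        L -= 2.0 * _plogp(q[lab])
        L += _plogp(q[lab] + sum_p[lab])
    return L


def optimize_partition(net: CTNetwork, trials: int = 20,
                       seed: Optional[int] = None) -> MotifResult:
    """Heuristic map-equation minimization on a connected network.

    Each trial starts from singleton modules, runs greedy node-move sweeps
    (every node to the neighboring module that most decreases L, repeated
    until stable), then merge-and-fine-tune passes over connected module
    pairs, iterating both until neither improves.  Node orders are shuffled
    per trial from a seeded generator; the minimum-L partition over all
    trials wins.  Deterministic for fixed ``seed`` and ``trials``.
    """
    if trials < 1:
        raise ValueError(f"trials must be >= 1, got {trials}")
    if len(connected_components(net)) != 1:
        raise ValueError("optimize_partition requires a connected network; "
                         "split by connected component first (see detect_motifs)")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.graph.nodes)
    best_labels: Optional[dict[str, int]] = None
    best_L = math.inf
    for _ in range(trials):
        order = list(nodes)
        rng.shuffle(order)
        state = _State(net, {n: i for i, n in enumerate(nodes)})
        while True:
            L_before = state.codelength()
            _greedy_sweeps(state, order)
            state = _merge_and_finetune(net, state, order)
            if state.codelength() > L_before - _EPS:
                break
        L = state.codelength()
        if L < best_L - _EPS:
            best_L = L
            best_labels = dict(state.labels)
    partition = Partition(best_labels)
    terms = codelength(net, partition)
    return MotifResult(partition=partition, terms=terms, trials=trials, seed=seed)


def _set_partitions(items: list[str]):
    """All set partitions via restricted growth strings."""
    n = len(items)
    if n == 0:
        return
    a = [0] * n
    b = [0] * n  # b[i] = max(a[0..i-1])
    while True:
        groups: dict[int, list[str]] = {}
        for item, lab in zip(items, a):
            groups.setdefault(lab, []).append(item)
        yield list(groups.values())
        # next restricted growth string
        i = n - 1
        while i > 0 and a[i] == b[i] + 1:
            i -= 1
        if i == 0:
            return
        a[i] += 1
        m = max(b[i], a[i])
        for j in range(i + 1, n):
            a[j] = 0
            b[j] = m


def brute_force_partition(net: CTNetwork) -> tuple[Partition, float]:
    """Exhaustive minimum-codelength partition (oracle for small graphs).

    Refuses graphs with more than 10 nodes (Bell-number blow-up) and
    disconnected graphs (callers split first).  Ties break toward fewer
    modules, then lexicographically smaller sorted member sets.
    """
    nodes = sorted(net.graph.nodes)
    if len(nodes) > 10:
        raise ValueError(f"brute force limited to n <= 10, got n = {len(nodes)}")
    if len(connected_components(net)) != 1:
        raise ValueError("brute force requires a connected graph")
    state = _State(net, {n: 0 for n in nodes})

    def canon(groups: list[list[str]]) -> tuple:
        return tuple(sorted(tuple(sorted(g)) for g in groups))

    best: Optional[tuple[float, int, tuple, dict[str, int]]] = None
    for groups in _set_partitions(nodes):
        labels = {}
        for lab, group in enumerate(groups):
            for node in group:
                labels[node] = lab
        L = _labels_codelength(state, labels)
        key = (len(groups), canon(groups))
        if best is None or L < best[0] - _EPS or (
                abs(L - best[0]) <= _EPS and key < (best[1], best[2])):
            best = (L, key[0], key[1], labels)
    partition = Partition(best[3])
    return partition, best[0]


def _internal_weight(edges: list[tuple[str, str, float]], members: frozenset[str]) -> float:
    return sum(w for u, v, w in edges if u in members and v in members)


def _double_edge_swap(edges: list[tuple[str, str, float]],
                      rng: np.random.Generator,
                      n_attempts: int) -> list[tuple[str, str, float]]:
    """Degree-preserving rewiring: repeated double edge swaps.

    Swaps carry edge weights with the rewired edges; attempts creating
    self-loops or parallel edges are rejected.
    """
    edges = list(edges)
    present = {frozenset((u, v)) for u, v, _ in edges}
    m = len(edges)
    if m < 2 or n_attempts <= 0:
        return edges
    pairs = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (i, j), flip in zip(pairs, flips):
        if i == j:
            continue
        u, v, w1 = edges[i]
        x, y, w2 = edges[j]
        if flip:
            u, v = v, u
        # rewire (u,v),(x,y) -> (u,y),(x,v)
        if u == y or x == v:
            continue
        e1, e2 = frozenset((u, y)), frozenset((x, v))
        if e1 in present or e2 in present:
            continue
        present.discard(frozenset((u, v)))
        present.discard(frozenset((x, y)))
        present.add(e1)
        present.add(e2)
        edges[i] = (u, y, w1)
        edges[j] = (x, v, w2)
    return edges


def module_significance(net: CTNetwork, partition: Partition,
                        n_null: int = 999, seed: Optional[int] = None,
                        alpha: float = 0.05,
                        ) -> tuple[dict[int, float], dict[int, float], set[int]]:
    """Empirical per-module significance against a rewiring null.

    The statistic for each module is the total edge weight internal to its
    fixed node set.  The null resamples the network by degree-preserving
    double edge swaps (10 x |E| attempted swaps per replicate); the
    empirical p-value is ``(1 + #{null >= observed}) / (n_null + 1)``,
    adjusted across modules by Benjamini-Hochberg.  Modules whose adjusted
    p-value is below ``alpha`` form the KNMS set.  Size-1 modules have
    internal weight 0 and are trivially non-significant (p = 1).

    Nulls are drawn with the parallel Besag-Clifford construction: the
    observed graph is first rewired into a hub state, and every null chain
    restarts from that hub.  Because the swap chain is reversible, the
    observed graph and the nulls are exchangeable even when the chain has
    not fully mixed, which keeps the empirical p-values calibrated.
    """
    if n_null < 19:
        raise ValueError(f"n_null must be >= 19, got {n_null}")
    if partition.nodes() != set(net.graph.nodes):
        raise ValueError("partition does not cover the graph")
    rng = np.random.default_rng(seed)
    edges = [(u, v, d["weight"]) for u, v, d in net.graph.edges(data=True)]
    observed = {mid: _internal_weight(edges, members)
                for mid, members in partition.members.items()}
    counts = {mid: 0 for mid in observed}
    n_attempts = 10 * len(edges)
    hub = _double_edge_swap(edges, rng, n_attempts)
    for _ in range(n_null):
        null_edges = _double_edge_swap(hub, rng, n_attempts)
        for mid, members in partition.members.items():
            if _internal_weight(null_edges, members) >= observed[mid]:
                counts[mid] += 1
    p_values = {mid: (1 + c) / (n_null + 1) for mid, c in counts.items()}
    mids = sorted(p_values)
    _, q_arr, _, _ = multipletests([p_values[m] for m in mids], method="fdr_bh")
    q_values = dict(zip(mids, q_arr.tolist()))
    knms = {mid for mid in mids if q_values[mid] < alpha}
    return p_values, q_values, knms


def detect_motifs(net: CTNetwork, trials: int = 20, n_null: int = 999,
                  seed: Optional[int] = None, alpha: float = 0.05,
                  significance: bool = True) -> MotifResult:
    """Full motif detection on a possibly disconnected network.

    Each connected component is optimized independently; module ids are then
    renumbered globally and significance is assessed on the full network.
    Isolated nodes (degree 0) cannot be visited by the walk and are dropped
    with a warning.
    """
    isolated = [n for n in net.graph.nodes if net.graph.degree(n) == 0]
    if isolated:
        import logging
        logging.getLogger(__name__).warning(
            "dropping %d isolated node(s) before motif detection: %s",
            len(isolated), sorted(isolated)[:10])
        net = net.subgraph(n for n in net.graph.nodes if net.graph.degree(n) > 0)
    pieces = connected_components(net)
    rng = np.random.default_rng(seed)
    labels: dict[str, int] = {}
    offset = 0
    for piece in pieces:
        sub = net.subgraph(piece)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        result = optimize_partition(sub, trials=trials, seed=sub_seed)
        for node, mid in result.partition.assignment.items():
            labels[node] = offset + mid
        offset += result.partition.n_modules
    partition = Partition(labels)
    terms = codelength(net, partition)
    result = MotifResult(partition=partition, terms=terms, trials=trials, seed=seed)
    if significance:
        sig_seed = int(rng.integers(0, 2**31 - 1))
        p, q, knms = module_significance(net, partition, n_null=n_null,
                                         seed=sig_seed, alpha=alpha)
        result.p_values, result.q_values, result.knms = p, q, knms
    return result
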