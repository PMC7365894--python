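"""Independent oracles used by the test suite.

Deliberately naive implementations, kept separate from the package code
paths they check: an exact-rational map-equation evaluator, a combinatorial
hypergeometric tail, and a textbook Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import math
from fractions import Fraction
from math import comb


def rational_codelength(edges: list[tuple[str, str, int]],
                        modules: list[set[str]]) -> float:
    """Evaluate the map equation with exact rational visit/exit rates.

    ``edges`` carry integer weights; every rate (p_alpha, q_i, p_circ_i) is
    an exact :class:`fractions.Fraction`; only the final logarithms are
    floating point.  Follows the printed term definitions literally:
    L = q_enter * H(Q) + sum_i p_circ_i * H(P_i).
    """
    two_w = 2 * sum(w for _, _, w in edges)
    deg: dict[str, int] = {}
    for u, v, w in edges:
        deg[u] = deg.get(u, 0) + w
        deg[v] = deg.get(v, 0) + w
    p = {n: Fraction(d, two_w) for n, d in deg.items()}

    def where(node: str) -> int:
        for i, mod in enumerate(modules):
            if node in mod:
                return i
        raise KeyError(node)

    q = [Fraction(0)] * len(modules)
    for u, v, w in edges:
        iu, iv = where(u), where(v)
        if iu != iv:
            q[iu] += Fraction(w, two_w)
            q[iv] += Fraction(w, two_w)
    q_total = sum(q, Fraction(0))

    def h(probs: list[Fraction]) -> float:
        out = 0.0
        for pr in probs:
            if pr > 0:
                x = float(pr)
                out -= x * math.log2(x)
        return out

    L = float(q_total) * h([qi / q_total for qi in q]) if q_total > 0 else 0.0
    for i, mod in enumerate(modules):
        circ = q[i] + sum((p[a] for a in mod), Fraction(0))
        if circ > 0:
            L += float(circ) * h([q[i] / circ] + [p[a] / circ for a in mod])
    return L


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n) by direct enumeration."""
    total = comb(N, n)
    hi = min(K, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, hi + 1)) / total


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (textbook definition)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted
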