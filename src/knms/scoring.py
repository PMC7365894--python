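"""Contribution-coefficient scoring and module validation metrics.

Three metrics quantify how well detected modules represent the full
component-target network: (1) the contribution coefficient, the percentage
of min-max-normalized component-degree importance captured by a module;
(2) pathogenic-gene coverage, the percentage of disease genes in the full
network that the modules retain; and (3) pathway coverage, the percentage
of the reference enriched-pathway set recovered by the modules' own
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import PathwayCollection

__all__ = [
    "EnrichmentResult",
    "normalized_importance",
    "contribution_coefficient",
    "gene_coverage",
    "enrich_pathways",
    "pathway_coverage",
    "round1",
]

log = logging.getLogger(__name__)


def round1(x: float) -> float:
    """One-decimal rounding (round-half-even), applied only at reporting."""
    return round(x, 1)


def normalized_importance(degrees: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize component degrees: R = (d - d_min) / (d_max - d_min).

    R is the unitless importance of a component in [0, 1].  If all degrees
    coincide the formula is 0/0; every component then gets R = 1 (equal
    importance keeps downstream ratios defined and additive).
    """
    if not degrees:
        raise ValueError("empty degree map")
    values = list(degrees.values())
    d_min, d_max = min(values), max(values)
    if d_max == d_min:
        return {c: 1.0 for c in degrees}
    return {c: (d - d_min) / (d_max - d_min) for c, d in degrees.items()}


def contribution_coefficient(module_components: Iterable[str],
                             network_degrees: Mapping[str, float]) -> float:
    """CC of a module: 100 x sum of its R values over the network's R total.

    ``network_degrees`` maps every component of the full network to its
    degree; R is normalized over that full map, so CC of the complete
    component set is exactly 100 and CC is additive over disjoint modules.
    Target nodes must be excluded by the caller.
    """
    module = set(module_components)
    missing = module - set(network_degrees)
    if missing:
        raise ValueError(f"module components absent from degree map: {sorted(missing)}")
    r = normalized_importance(network_degrees)
    denom = sum(r.values())
    if denom <= 0:
        raise ValueError("total importance is zero; degenerate degree map")
    return 100.0 * sum(r[c] for c in module) / denom


def gene_coverage(knms_genes: Iterable[str], ct_genes: Iterable[str],
                  disease_genes: Iterable[str]) -> tuple[Optional[float], int, int]:
    """Pathogenic-gene coverage of the modules relative to the full network.

    Returns ``(percent, n_knms_disease, n_ct_disease)`` where percent is
    100 x |knms ∩ disease| / |ct ∩ disease| rounded to one decimal, or
    ``None`` (flagged undefined) when the network holds no disease genes.
    """
    knms = set(knms_genes)
    ct = set(ct_genes)
    disease = set(disease_genes)
    if not knms <= ct:
        log.warning("module genes not contained in network genes: %s",
                    sorted(knms - ct)[:10])
    k_knms = len(knms & disease)
    k_ct = len(ct & disease)
    if k_ct == 0:
        log.warning("no pathogenic genes in the network; coverage undefined")
        return None, k_knms, k_ct
    return round1(100.0 * k_knms / k_ct), k_knms, k_ct


@dataclass(frozen=True)
class PathwayTest:
    pathway_id: str
    description: str
    k: int  # overlap
    n: int  # query size
    K: int  # pathway size (within background)
    N: int  # background size
    p_value: float
    q_value: Optional[float] = None


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway hypergeometric tests plus the enriched set at the cutoff."""

    tests: tuple[PathwayTest, ...]
    enriched: frozenset[str]
    cutoff: float
    adjust: str


def enrich_pathways(query_genes: Iterable[str], pathways: PathwayCollection,
                    background: Optional[Iterable[str]] = None,
                    cutoff: float = 0.05, adjust: str = "none") -> EnrichmentResult:
    """One-sided hypergeometric (upper tail) enrichment of a gene set.

    For each pathway with K of the N background genes, a query of n genes
    overlapping k of them scores p = P(X >= k), X ~ Hypergeom(N, K, n).
    ``background`` defaults to the union of all pathway genes; query genes
    outside it are dropped with a warning.  ``adjust`` is ``none`` (cutoff on
    raw p, the conventional 0.05 criterion) or ``bh`` for Benjamini-Hochberg.
    Tests are ordered by p-value then pathway id.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    bg = set(background) if background is not None else pathways.all_genes()
    bg = {g.upper() for g in bg}
    if not bg:
        raise ValueError("empty enrichment background")
    query = {g.upper() for g in query_genes}
    dropped = query - bg
    if dropped:
        log.warning("dropping %d query genes outside the background", len(dropped))
    query &= bg
    N, n = len(bg), len(query)

    tests = []
    for pid in sorted(pathways.pathways):
        desc, genes = pathways.pathways[pid]
        genes = genes & bg
        K = len(genes)
        k = len(query & genes)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        tests.append(PathwayTest(pid, desc, k, n, K, N, min(p, 1.0)))

    if adjust == "bh" and tests:
        _, q_arr, _, _ = multipletests([t.p_value for t in tests], method="fdr_bh")
        tests = [PathwayTest(t.pathway_id, t.description, t.k, t.n, t.K, t.N,
                             t.p_value, float(q)) for t, q in zip(tests, q_arr)]
    tests.sort(key=lambda t: (t.p_value, t.pathway_id))
    crit = (lambda t: t.q_value) if adjust == "bh" else (lambda t: t.p_value)
    enriched = frozenset(t.pathway_id for t in tests if crit(t) <= cutoff)
    return EnrichmentResult(tests=tuple(tests), enriched=enriched,
                            cutoff=cutoff, adjust=adjust)


def pathway_coverage(subset_pathways: Iterable[str],
                     reference_pathways: Iterable[str]) -> Optional[float]:
    """Percent of the reference pathway set recovered by the subset.

    100 x |subset ∩ reference| / |reference| to one decimal; ``None``
    (flagged undefined) for an empty reference.
    """
    subset = set(subset_pathways)
    reference = set(reference_pathways)
    if not reference:
        log.warning("empty reference pathway set; coverage undefined")
        return None
    return round1(100.0 * len(subset & reference) / len(reference))
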