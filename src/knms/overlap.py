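"""Cross-formula common/unique component accounting (Venn arithmetic).

Components are identified by normalized name (the same molecule appears
under different formula-local ids and herbs), so all set operations here key
on :func:`knms.types.normalize_name`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .types import Component, normalize_name

__all__ = ["VennRegion", "OverlapResult", "component_name_sets", "common_unique"]


@dataclass(frozen=True)
class VennRegion:
    """One of the 2^k - 1 regions of a k-set Venn diagram."""

    bitmask: int
    formulas: tuple[str, ...]
    count: int
    members: frozenset[str]


@dataclass(frozen=True)
class OverlapResult:
    formulas: tuple[str, ...]
    common: int          # shared by all formulas
    unique: dict[str, int]   # per formula: members not shared by all
    exclusive: dict[str, int]  # per formula: members found nowhere else
    regions: tuple[VennRegion, ...]


def component_name_sets(components: Sequence[Component]) -> dict[str, set[str]]:
    """Per-formula sets of normalized component names.

    A molecule repeated across herbs within one formula counts once.
    """
    sets: dict[str, set[str]] = {}
    for c in components:
        sets.setdefault(c.formula, set()).add(c.norm_name)
    return sets


def common_unique(sets: Mapping[str, set[str]]) -> OverlapResult:
    """Common and unique component counts across formulas, plus all regions.

    ``common`` is the size of the intersection of every formula's set.  A
    formula's ``unique`` count is the number of its components *not shared
    by all formulas* (its set size minus the common core) -- the convention
    under which the counts of the three studied prescriptions decompose as
    124 = 31 + 93, 120 = 31 + 89, 48 = 31 + 17.  ``exclusive`` additionally
    reports the stricter count of components found in no other formula.
    """
    if len(sets) < 2:
        raise ValueError("overlap analysis needs at least two formulas")
    formulas = tuple(sorted(sets))
    universe: set[str] = set().union(*sets.values())
    core = set.intersection(*(sets[f] for f in formulas))

    regions = []
    for bitmask in range(1, 2 ** len(formulas)):
        inside = [f for i, f in enumerate(formulas) if bitmask >> i & 1]
        outside = [f for f in formulas if f not in inside]
        members = set.intersection(*(sets[f] for f in inside))
        for f in outside:
            members -= sets[f]
        regions.append(VennRegion(bitmask=bitmask, formulas=tuple(inside),
                                  count=len(members), members=frozenset(members)))
    assert sum(r.count for r in regions) == len(universe)

    unique = {f: len(sets[f]) - len(core) for f in formulas}
    exclusive = {f: len(sets[f] - set().union(*(sets[g] for g in formulas if g != f)))
                 for f in formulas}
    return OverlapResult(formulas=formulas, common=len(core), unique=unique,
                         exclusive=exclusive, regions=tuple(regions))
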