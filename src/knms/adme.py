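"""ADME screening: the combined Lipinski + OB + DL filter.

Active components are those that jointly satisfy a rule-of-five style
property profile (molecular weight, hydrogen-bond donors/acceptors, logP
window, rotatable bonds) together with oral bioavailability (OB >= 30%) and
drug-likeness (DL >= 0.14) thresholds.  The filter is a strict conjunction
of all seven rules.

Bounds are inclusive by default.  The published retained sets contain
components sitting exactly on the stated limits (HDON = 5, HACC = 10,
RBN = 10, DL = 0.14, OB very close to 30), so inclusive comparisons are the
only reading consistent with the data; ``inclusive=False`` reproduces the
literal strict-inequality wording instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from .types import Component

__all__ = ["ScreenCriteria", "RuleRecord", "evaluate_rules", "adme_filter"]

RULES = ("mw", "hdon", "hacc", "logp", "rbn", "ob", "dl")


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds for the seven screening rules."""

    mw_max: float = 500.0
    hdon_max: int = 5
    hacc_max: int = 10
    logp_min: float = -2.0
    logp_max: float = 5.0
    rbn_max: int = 10
    ob_min: float = 30.0
    dl_min: float = 0.14
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not self.logp_min < self.logp_max:
            raise ValueError("logp_min must be below logp_max")
        for name in ("mw_max", "logp_min", "logp_max", "ob_min", "dl_min"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class RuleRecord:
    """Per-rule pass/fail outcome for one component."""

    component_id: str
    passed: dict[str, bool] = field(default_factory=dict)

    @property
    def overall(self) -> bool:
        return all(self.passed.values())

    @property
    def failing(self) -> set[str]:
        return {rule for rule, ok in self.passed.items() if not ok}


def evaluate_rules(c: Component, criteria: ScreenCriteria = ScreenCriteria()) -> RuleRecord:
    """Evaluate all seven screening rules on one component.

    Raises :class:`ValueError` naming the property if any numeric field is
    missing or NaN.
    """
    for attr in ("mw", "logp", "hdon", "hacc", "rbn", "ob", "dl"):
        v = getattr(c, attr)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{c.id}: missing property {attr!r}")

    if criteria.inclusive:
        le = lambda a, b: a <= b
        ge = lambda a, b: a >= b
    else:
        le = lambda a, b: a < b
        ge = lambda a, b: a > b

    passed = {
        "mw": le(c.mw, criteria.mw_max),
        "hdon": le(c.hdon, criteria.hdon_max),
        "hacc": le(c.hacc, criteria.hacc_max),
        "logp": le(c.logp, criteria.logp_max) and ge(c.logp, criteria.logp_min),
        "rbn": le(c.rbn, criteria.rbn_max),
        "ob": ge(c.ob, criteria.ob_min),
        "dl": ge(c.dl, criteria.dl_min),
    }
    return RuleRecord(component_id=c.id, passed=passed)


def adme_filter(components: Sequence[Component],
                criteria: ScreenCriteria = ScreenCriteria(),
                ) -> tuple[list[Component], list[RuleRecord]]:
    """Split components into retained actives and a rejection log.

    Returns ``(retained, rejections)``: retained preserves input order; each
    rejection records which rules failed.  A component with a missing or NaN
    property is rejected with the pseudo-rule ``missing`` rather than being
    passed silently.
    """
    retained: list[Component] = []
    rejections: list[RuleRecord] = []
    for c in components:
        try:
            record = evaluate_rules(c, criteria)
        except ValueError:
            rejections.append(RuleRecord(component_id=c.id, passed={"missing": False}))
            continue
        if record.overall:
            retained.append(c)
        else:
            rejections.append(record)
    return retained, rejections
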