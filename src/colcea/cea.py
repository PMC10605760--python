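"""Incremental cost-effectiveness table construction.

Each candidate strategy is compared against a single designated comparator:
incremental cost and incremental QALYs are plain differences of the lifetime
totals, the ICER is their ratio with cost-effectiveness-plane quadrant
semantics attached, and each row receives exactly one interpretation label:

* ``base case`` — the comparator row itself;
* ``dominated by <X>`` — some other strategy costs no more and yields no
  fewer QALYs, with at least one strict inequality (strict pairwise
  dominance; the cheapest such dominator is named);
* ``cost saving`` — cheaper than the comparator without losing QALYs;
* ``cost effective`` — more costly and more effective with an ICER at or
  below the willingness-to-pay ceiling;
* ``not cost effective`` — everything else (including south-west quadrant
  trades: saving money by giving up QALYs is never labelled cost effective
  here, whatever the ratio).

ICERs are computed from unrounded totals; rounding happens only at
presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import StrategyResult

__all__ = [
    "Incremental",
    "ICER",
    "CEARow",
    "incremental",
    "icer",
    "nmb",
    "classify",
    "build_cea_table",
    "LABEL_BASE",
    "LABEL_COST_SAVING",
    "LABEL_COST_EFFECTIVE",
    "LABEL_NOT_COST_EFFECTIVE",
]

LABEL_BASE = "base case"
LABEL_COST_SAVING = "cost saving compared to base case"
LABEL_COST_EFFECTIVE = "cost effective compared to base case"
LABEL_NOT_COST_EFFECTIVE = "not cost effective compared to base case"


@dataclass(frozen=True)
class Incremental:
    delta_cost: float
    delta_qaly: float


@dataclass(frozen=True)
class ICER:
    """Ratio plus quadrant tag; ``value`` is None when dQALY = 0."""

    value: float | None
    quadrant: str  # "NE" | "SW" | "dominant" | "dominated" | "undefined"


def incremental(result: StrategyResult, base: StrategyResult) -> Incremental:
    """Component-wise difference strategy minus comparator."""
    return Incremental(result.cost - base.cost, result.qaly - base.qaly)


def icer(delta_cost: float, delta_qaly: float) -> ICER:
    """ICER with cost-effectiveness-plane quadrant semantics.

    NE: costs more, gains QALYs (cost per QALY gained).  SW: saves money,
    loses QALYs (savings per QALY lost).  ``dominant``/``dominated`` cover
    the unambiguous quadrants; a zero QALY difference leaves the ratio
    undefined (that is a value, not an error).
    """
    if delta_qaly == 0.0:
        if delta_cost == 0.0:
            return ICER(None, "undefined")
        return ICER(None, "dominant" if delta_cost < 0 else "dominated")
    ratio = delta_cost / delta_qaly
    if delta_cost > 0 and delta_qaly > 0:
        return ICER(ratio, "NE")
    if delta_cost < 0 and delta_qaly < 0:
        return ICER(ratio, "SW")
    if delta_qaly > 0:  # delta_cost <= 0
        return ICER(ratio, "dominant")
    return ICER(ratio, "dominated")


def nmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Net monetary benefit: wtp x dQALY - dCost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be non-negative")
    return wtp * delta_qaly - delta_cost


@dataclass
class CEARow:
    strategy: str
    cost: float
    ly: float
    qaly: float
    delta_cost: float | None = None
    delta_qaly: float | None = None
    icer: ICER | None = None
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "cost": self.cost,
            "ly": self.ly,
            "qaly": self.qaly,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": None if self.icer is None else self.icer.value,
            "quadrant": None if self.icer is None else self.icer.quadrant,
            "label": self.label,
        }


def _strictly_dominates(a: CEARow, b: CEARow) -> bool:
    return (a.cost <= b.cost and a.qaly >= b.qaly
            and (a.cost < b.cost or a.qaly > b.qaly))


def classify(rows: list[CEARow], wtp: float) -> list[CEARow]:
    """Assign one interpretation label to each non-base row.

    Rows must already carry incrementals vs a common comparator (the base row
    has ``delta_cost is None``).  The result is independent of row order;
    with several dominators the cheapest (then most effective) one is named.
    """
    names = [r.strategy for r in rows]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names in CEA table")
    for row in rows:
        if row.delta_cost is None:  # comparator
            row.label = LABEL_BASE
            continue
        dominators = [o for o in rows if o is not row
                      and _strictly_dominates(o, row)]
        if dominators:
            best = min(dominators, key=lambda o: (o.cost, -o.qaly))
            row.label = f"dominated by {best.strategy}"
            continue
        if row.delta_cost < 0 and row.delta_qaly >= 0:
            row.label = LABEL_COST_SAVING
            continue
        tagged = icer(row.delta_cost, row.delta_qaly)
        if tagged.quadrant == "NE" and tagged.value is not None \
                and tagged.value <= wtp:
            row.label = LABEL_COST_EFFECTIVE
        else:
            row.label = LABEL_NOT_COST_EFFECTIVE
    return rows


def build_cea_table(results: list[StrategyResult], base_name: str,
                    wtp: float, discounted_ly: bool = False) -> list[CEARow]:
    """Full incremental table vs one comparator, labelled at the given WTP.

    Costs and QALYs are the discounted totals.  The LY column defaults to the
    undiscounted life expectancy, the form in which survival is customarily
    reported alongside discounted outcomes; pass ``discounted_ly=True`` for
    the discounted variant.
    """
    by_name = {r.strategy: r for r in results}
    if base_name not in by_name:
        raise KeyError(f"comparator {base_name!r} not among results")
    base = by_name[base_name]
    rows = []
    for res in results:
        ly = res.ly if discounted_ly else res.ly_undiscounted
        row = CEARow(res.strategy, res.cost, ly, res.qaly)
        if res.strategy != base_name:
            inc = incremental(res, base)
            row.delta_cost = inc.delta_cost
            row.delta_qaly = inc.delta_qaly
            row.icer = icer(inc.delta_cost, inc.delta_qaly)
        rows.append(row)
    return classify(rows, wtp)
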