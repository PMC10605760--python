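"""Per-course chemotherapy costing.

A course is the full sequence of cycles of one regimen (e.g. twelve
two-weekly cycles of FOLFOX).  Drug cost is strictly proportional to the
milligrams delivered: body-surface-area-scaled dose x days x cycles priced
at the per-milligram cost of the package, with no vial-rounding (the model
assumes no product wastage).  Administration cost is the per-visit fee of
the delivery modality times the visits per course; oral dispensing carries
no administration fee.  Non-medical cost (food and transportation) accrues
per hospital visit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import UnitCosts

__all__ = [
    "DoseRule",
    "Regimen",
    "CourseCost",
    "bsa_mosteller",
    "course_total_mg",
    "course_drug_cost",
    "course_admin_cost",
    "visit_nonmedical_cost",
    "course_cost",
    "course_breakdown_table",
]


@dataclass(frozen=True)
class DoseRule:
    """Dosing of one agent within a regimen.

    ``dose_mg_per_m2`` is per day when ``days_per_cycle > 1``, otherwise per
    administration (a single-day administration counts as one day).
    """

    agent: str
    dose_mg_per_m2: float
    days_per_cycle: int = 1
    cycles_per_course: int = 1
    route: str = "iv_infusion"  # oral | iv_bolus | iv_infusion | iv_cont_infusion


@dataclass(frozen=True)
class Regimen:
    name: str
    dose_rules: tuple[DoseRule, ...]
    admin_modality: str  # opd_bolus | opd_infusion | ipd_infusion | dispensing
    care_setting: str    # OPD | IPD
    visits_per_course: int = 0

    @property
    def is_oral_backbone(self) -> bool:
        """True when the regimen's fluoropyrimidine is taken orally."""
        return any(r.route == "oral" for r in self.dose_rules)


@dataclass(frozen=True)
class CourseCost:
    drug: float
    administration: float
    nonmedical: float

    @property
    def total(self) -> float:
        return self.drug + self.administration + self.nonmedical

    @property
    def payer(self) -> float:
        """Drug plus administration only (payer-perspective budgeting)."""
        return self.drug + self.administration


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by Mosteller's formula.

    sqrt(height_cm x weight_kg / 3600).
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def course_total_mg(rule: DoseRule, bsa: float) -> float:
    """Total milligrams of one agent over a full course at the given BSA."""
    return rule.dose_mg_per_m2 * bsa * rule.days_per_cycle * rule.cycles_per_course


def course_drug_cost(regimen: Regimen, bsa: float, unit_costs: "UnitCosts") -> float:
    """Drug acquisition cost of a full course (USD), per-mg pricing."""
    total = 0.0
    for rule in regimen.dose_rules:
        try:
            price = unit_costs.drug_prices[rule.agent]
        except KeyError:
            raise KeyError(
                f"no unit price for agent {rule.agent!r} in regimen {regimen.name!r}"
            ) from None
        total += course_total_mg(rule, bsa) * price.usd_per_mg
    return total


def course_admin_cost(regimen: Regimen, unit_costs: "UnitCosts") -> float:
    """Administration cost of a full course: visits x modality fee."""
    try:
        fee = unit_costs.administration[regimen.admin_modality].value
    except KeyError:
        raise KeyError(
            f"unknown administration modality {regimen.admin_modality!r}"
        ) from None
    return regimen.visits_per_course * fee


def visit_nonmedical_cost(visits: float, unit_costs: "UnitCosts") -> float:
    """Food plus transportation cost for a number of hospital visits."""
    if visits < 0:
        raise ValueError("visit count must be non-negative")
    return visits * unit_costs.nonmedical_per_visit


def course_cost(regimen: Regimen, bsa: float, unit_costs: "UnitCosts") -> CourseCost:
    """Full per-course cost breakdown for one regimen."""
    return CourseCost(
        drug=course_drug_cost(regimen, bsa, unit_costs),
        administration=course_admin_cost(regimen, unit_costs),
        nonmedical=visit_nonmedical_cost(regimen.visits_per_course, unit_costs),
    )


def course_breakdown_table(regimen: Regimen, bsa: float,
                           unit_costs: "UnitCosts") -> list[dict]:
    """Per-agent rows (agent, mg, USD) plus administration and non-medical."""
    rows = []
    for rule in regimen.dose_rules:
        mg = course_total_mg(rule, bsa)
        usd = mg * unit_costs.drug_prices[rule.agent].usd_per_mg
        rows.append({"item": rule.agent, "mg": mg, "usd": usd})
    rows.append({"item": "administration", "mg": float("nan"),
                 "usd": course_admin_cost(regimen, unit_costs)})
    rows.append({"item": "non-medical", "mg": float("nan"),
                 "usd": visit_nonmedical_cost(regimen.visits_per_course, unit_costs)})
    return rows
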