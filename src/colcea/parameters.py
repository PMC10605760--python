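"""Model inputs for the stage III colorectal-cancer treatment decision model.

Every quantity the model consumes is collected into a single validated
:class:`ModelParameters` bundle: global settings (cohort start age, cycle
length, discount rate, willingness-to-pay ceiling), annual transition
probabilities by regimen and time-in-state, EQ-5D utility weights by health
state and administration route, unit costs (drug packages, administration
visits, annual care, food and transportation per visit), hospital visit
schedules, chemotherapy regimen definitions, and budget-impact inputs.

The base case ships as a bundled YAML fixture (``data/params_basecase.yaml``)
holding the published Thai 2021-USD input set.  Probabilities and costs that
were published without a standard error carry ``se = None``; imputation of a
spread for probabilistic analyses is a declared policy of the sensitivity
module, not of this one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml

from .costing import DoseRule, Regimen

__all__ = [
    "Estimate",
    "Settings",
    "TransitionSet",
    "UtilitySet",
    "DrugPrice",
    "UnitCosts",
    "AnnualCareCosts",
    "VisitSchedule",
    "BIAInputs",
    "ModelParameters",
    "Violation",
    "SchemaError",
    "load_parameters",
    "save_parameters",
    "load_basecase",
    "validate",
    "REGIMEN_NAMES",
    "FIRST_LINE_REGIMENS",
    "SECOND_LINE_REGIMENS",
    "SD_BANDS",
    "PD_BANDS",
    "ADMIN_MODALITIES",
    "CARE_COST_KEYS",
    "STATE_VISIT_KEYS",
]

REGIMEN_NAMES = ("5-FU/LV", "capecitabine", "FOLFOX", "CAPOX", "FOLFIRI")
FIRST_LINE_REGIMENS = ("5-FU/LV", "capecitabine", "FOLFOX", "CAPOX")
SECOND_LINE_REGIMENS = ("FOLFOX", "CAPOX", "FOLFIRI")

#: Time-in-state bands for stable disease (years since diagnosis) and
#: progressive disease (years since progression).  The last band is open.
SD_BANDS = ("year1", "year2", "year3", "year4", "subsequent")
PD_BANDS = ("year1", "year2", "year3", "subsequent")

ADMIN_MODALITIES = ("opd_bolus", "opd_infusion", "ipd_infusion", "dispensing")

CARE_COST_KEYS = (
    "sd_year1_opd",
    "sd_year1_ipd",
    "sd_year2",
    "sd_year3plus",
    "pd_year1_opd",
    "pd_year1_ipd",
    "pd_year2",
    "pd_year3plus",
)

STATE_VISIT_KEYS = (
    "sd_year1_off",
    "sd_year2",
    "sd_year3plus",
    "pd_year1_off",
    "pd_year2",
    "pd_year3plus",
)


class SchemaError(ValueError):
    """A config file is missing a required key or has the wrong shape."""


@dataclass
class Estimate:
    """A point value with an optional standard error.

    ``se is None`` means the source published no spread for this quantity;
    downstream analyses decide how (and whether) to impute one.
    """

    value: float
    se: float | None = None

    def __float__(self) -> float:  # convenience for arithmetic
        return float(self.value)


@dataclass
class Settings:
    start_age: float = 63.0
    cycle_length: float = 1.0
    discount_rate: float = 0.03
    wtp_threshold: float = 5003.0
    horizon_age: float = 100.0
    bsa: float = 1.7
    body_weight: float = 60.0
    treated_fraction_of_first_cycle: float = 0.5


@dataclass
class TransitionSet:
    """Annual disease transition probabilities by regimen and time in state.

    ``sd_to_death`` maps a first-line regimen to one probability per band in
    :data:`SD_BANDS`; ``pd_to_death`` maps a second-line regimen to one per
    band in :data:`PD_BANDS`.  These are disease-specific probabilities; the
    background all-cause component is combined in the mortality module.
    """

    sd_to_pd: dict[str, Estimate]
    sd_to_death: dict[str, dict[str, Estimate]]
    pd_to_death: dict[str, dict[str, Estimate]]


@dataclass
class UtilitySet:
    sd_on_iv: Estimate
    sd_on_oral: Estimate
    sd_off: Estimate
    pd_on_iv: Estimate
    pd_off: Estimate


@dataclass
class DrugPrice:
    usd_per_package: float
    mg_per_package: float
    se: float | None = None

    @property
    def usd_per_mg(self) -> float:
        return self.usd_per_package / self.mg_per_package


@dataclass
class UnitCosts:
    drug_prices: dict[str, DrugPrice]
    administration: dict[str, Estimate]  # keyed by ADMIN_MODALITIES
    food: Estimate
    transportation: Estimate

    @property
    def nonmedical_per_visit(self) -> float:
        return self.food.value + self.transportation.value


@dataclass
class AnnualCareCosts:
    """Other healthcare costs (USD per person-year) by state and year band.

    Year 1 in each state has an outpatient and an inpatient variant; the one
    applied depends on the care setting of the regimen delivered that year.
    """

    costs: dict[str, Estimate]  # keyed by CARE_COST_KEYS

    def __getitem__(self, key: str) -> Estimate:
        return self.costs[key]


@dataclass
class VisitSchedule:
    per_course: dict[str, int]  # regimen -> visits per chemotherapy course
    state_year: dict[str, float]  # STATE_VISIT_KEYS -> visits per period


@dataclass
class BIAInputs:
    population: float
    incidence_per_100k: float = 39.72
    accessibility: float = 0.80
    population_growth: float = 0.003
    horizon_years: int = 5


@dataclass
class ModelParameters:
    settings: Settings
    transitions: TransitionSet
    utilities: UtilitySet
    unit_costs: UnitCosts
    care_costs: AnnualCareCosts
    visits: VisitSchedule
    regimens: dict[str, Regimen]
    bia: BIAInputs


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str

    def __str__(self) -> str:
        return f"{self.field}: {self.rule}"


# ---------------------------------------------------------------------------
# Loading / saving


def _require(mapping: dict, key: str, context: str) -> Any:
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise SchemaError(f"missing required key {context}.{key}") from None


def _estimate(raw: Any, context: str) -> Estimate:
    if isinstance(raw, dict):
        return Estimate(float(_require(raw, "value", context)),
                        None if raw.get("se") is None else float(raw["se"]))
    if isinstance(raw, (int, float)):
        return Estimate(float(raw))
    raise SchemaError(f"{context} must be a number or a {{value, se}} mapping")


def _parse_regimen(name: str, raw: dict, visits: VisitSchedule) -> Regimen:
    ctx = f"regimens.{name}"
    rules = []
    for i, r in enumerate(_require(raw, "dose_rules", ctx)):
        rctx = f"{ctx}.dose_rules[{i}]"
        rules.append(
            DoseRule(
                agent=_require(r, "agent", rctx),
                dose_mg_per_m2=float(_require(r, "dose_mg_per_m2", rctx)),
                days_per_cycle=int(r.get("days_per_cycle", 1)),
                cycles_per_course=int(_require(r, "cycles_per_course", rctx)),
                route=r.get("route", "iv_infusion"),
            )
        )
    return Regimen(
        name=name,
        dose_rules=tuple(rules),
        admin_modality=_require(raw, "admin_modality", ctx),
        care_setting=_require(raw, "care_setting", ctx),
        visits_per_course=int(visits.per_course.get(name, 0)),
    )


def _params_from_dict(doc: dict) -> ModelParameters:
    s = _require(doc, "settings", "root")
    settings = Settings(
        start_age=float(_require(s, "start_age", "settings")),
        cycle_length=float(s.get("cycle_length", 1.0)),
        discount_rate=float(_require(s, "discount_rate", "settings")),
        wtp_threshold=float(_require(s, "wtp_threshold", "settings")),
        horizon_age=float(s.get("horizon_age", 100.0)),
        bsa=float(_require(s, "bsa", "settings")),
        body_weight=float(s.get("body_weight", 60.0)),
        treated_fraction_of_first_cycle=float(
            s.get("treated_fraction_of_first_cycle", 0.5)
        ),
    )

    t = _require(doc, "transitions", "root")
    sd_to_pd = {
        reg: _estimate(v, f"transitions.sd_to_pd.{reg}")
        for reg, v in _require(t, "sd_to_pd", "transitions").items()
    }
    sd_to_death = {
        reg: {
            band: _estimate(_require(bands, band, f"transitions.sd_to_death.{reg}"),
                            f"transitions.sd_to_death.{reg}.{band}")
            for band in SD_BANDS
        }
        for reg, bands in _require(t, "sd_to_death", "transitions").items()
    }
    pd_to_death = {
        reg: {
            band: _estimate(_require(bands, band, f"transitions.pd_to_death.{reg}"),
                            f"transitions.pd_to_death.{reg}.{band}")
            for band in PD_BANDS
        }
        for reg, bands in _require(t, "pd_to_death", "transitions").items()
    }
    transitions = TransitionSet(sd_to_pd, sd_to_death, pd_to_death)

    u = _require(doc, "utilities", "root")
    utilities = UtilitySet(
        **{k: _estimate(_require(u, k, "utilities"), f"utilities.{k}")
           for k in ("sd_on_iv", "sd_on_oral", "sd_off", "pd_on_iv", "pd_off")}
    )

    c = _require(doc, "unit_costs", "root")
    drug_prices = {}
    for agent, raw in _require(c, "drug_prices", "unit_costs").items():
        ctx = f"unit_costs.drug_prices.{agent}"
        drug_prices[agent] = DrugPrice(
            usd_per_package=float(_require(raw, "usd_per_package", ctx)),
            mg_per_package=float(_require(raw, "mg_per_package", ctx)),
            se=None if raw.get("se") is None else float(raw["se"]),
        )
    administration = {
        m: _estimate(_require(_require(c, "administration", "unit_costs"), m,
                              "unit_costs.administration"),
                     f"unit_costs.administration.{m}")
        for m in ADMIN_MODALITIES
    }
    unit_costs = UnitCosts(
        drug_prices=drug_prices,
        administration=administration,
        food=_estimate(_require(c, "food", "unit_costs"), "unit_costs.food"),
        transportation=_estimate(_require(c, "transportation", "unit_costs"),
                                 "unit_costs.transportation"),
    )

    cc = _require(doc, "care_costs", "root")
    care_costs = AnnualCareCosts(
        {k: _estimate(_require(cc, k, "care_costs"), f"care_costs.{k}")
         for k in CARE_COST_KEYS}
    )

    v = _require(doc, "visits", "root")
    visits = VisitSchedule(
        per_course={k: int(val)
                    for k, val in _require(v, "per_course", "visits").items()},
        state_year={k: float(_require(_require(v, "state_year", "visits"), k,
                                      "visits.state_year"))
                    for k in STATE_VISIT_KEYS},
    )

    regimens = {
        name: _parse_regimen(name, raw, visits)
        for name, raw in _require(doc, "regimens", "root").items()
    }

    b = _require(doc, "bia", "root")
    bia = BIAInputs(
        population=float(_require(b, "population", "bia")),
        incidence_per_100k=float(_require(b, "incidence_per_100k", "bia")),
        accessibility=float(_require(b, "accessibility", "bia")),
        population_growth=float(_require(b, "population_growth", "bia")),
        horizon_years=int(b.get("horizon_years", 5)),
    )

    return ModelParameters(settings, transitions, utilities, unit_costs,
                           care_costs, visits, regimens, bia)


def load_parameters(path: str | Path) -> ModelParameters:
    """Load and parse a YAML parameter file into a :class:`ModelParameters`.

    Raises :class:`SchemaError` naming the first missing key, or
    ``yaml.YAMLError`` if the file does not parse at all.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError("parameter file must contain a mapping at top level")
    return _params_from_dict(doc)


def load_basecase() -> ModelParameters:
    """Load the bundled published base-case input set."""
    ref = resources.files("colcea.data").joinpath("params_basecase.yaml")
    with resources.as_file(ref) as path:
        return load_parameters(path)


def _estimate_to_raw(e: Estimate) -> Any:
    return e.value if e.se is None else {"value": e.value, "se": e.se}


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    """Write a ModelParameters back to YAML (round-trips with the loader)."""
    p = params
    doc: dict[str, Any] = {
        "settings": dataclasses.asdict(p.settings),
        "transitions": {
            "sd_to_pd": {k: _estimate_to_raw(v)
                         for k, v in p.transitions.sd_to_pd.items()},
            "sd_to_death": {reg: {b: _estimate_to_raw(e) for b, e in bands.items()}
                            for reg, bands in p.transitions.sd_to_death.items()},
            "pd_to_death": {reg: {b: _estimate_to_raw(e) for b, e in bands.items()}
                            for reg, bands in p.transitions.pd_to_death.items()},
        },
        "utilities": {k: _estimate_to_raw(getattr(p.utilities, k))
                      for k in ("sd_on_iv", "sd_on_oral", "sd_off",
                                "pd_on_iv", "pd_off")},
        "unit_costs": {
            "drug_prices": {
                agent: {"usd_per_package": d.usd_per_package,
                        "mg_per_package": d.mg_per_package,
                        **({"se": d.se} if d.se is not None else {})}
                for agent, d in p.unit_costs.drug_prices.items()
            },
            "administration": {m: _estimate_to_raw(e)
                               for m, e in p.unit_costs.administration.items()},
            "food": _estimate_to_raw(p.unit_costs.food),
            "transportation": _estimate_to_raw(p.unit_costs.transportation),
        },
        "care_costs": {k: _estimate_to_raw(e) for k, e in p.care_costs.costs.items()},
        "visits": {"per_course": dict(p.visits.per_course),
                   "state_year": dict(p.visits.state_year)},
        "regimens": {
            name: {
                "dose_rules": [
                    {"agent": r.agent, "dose_mg_per_m2": r.dose_mg_per_m2,
                     "days_per_cycle": r.days_per_cycle,
                     "cycles_per_course": r.cycles_per_course, "route": r.route}
                    for r in reg.dose_rules
                ],
                "admin_modality": reg.admin_modality,
                "care_setting": reg.care_setting,
            }
            for name, reg in p.regimens.items()
        },
        "bia": dataclasses.asdict(p.bia),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Validation


def _prob_fields(p: ModelParameters) -> Iterator[tuple[str, float]]:
    for reg, e in p.transitions.sd_to_pd.items():
        yield f"transitions.sd_to_pd.{reg}", e.value
    for reg, bands in p.transitions.sd_to_death.items():
        for band, e in bands.items():
            yield f"transitions.sd_to_death.{reg}.{band}", e.value
    for reg, bands in p.transitions.pd_to_death.items():
        for band, e in bands.items():
            yield f"transitions.pd_to_death.{reg}.{band}", e.value


def validate(params: ModelParameters) -> list[Violation]:
    """Check every type invariant; return one Violation per broken rule.

    An empty list means the bundle is internally consistent.  Violations are
    data, not exceptions: callers decide whether to abort.
    """
    v: list[Violation] = []
    s = params.settings
    if not (0.0 <= s.discount_rate <= 1.0):
        v.append(Violation("settings.discount_rate", "must be in [0, 1]"))
    if not s.start_age < s.horizon_age:
        v.append(Violation("settings.start_age", "must be below horizon_age"))
    if not s.bsa > 0:
        v.append(Violation("settings.bsa", "must be positive"))
    if not (0.0 <= s.treated_fraction_of_first_cycle <= 1.0):
        v.append(Violation("settings.treated_fraction_of_first_cycle",
                           "must be in [0, 1]"))

    for path, value in _prob_fields(params):
        if not (0.0 <= value <= 1.0):
            v.append(Violation(path, "probability must be in [0, 1]"))

    # Row-sum feasibility before background-mortality combination: in every
    # SD band the progression and disease-death probabilities must coexist.
    for reg, e in params.transitions.sd_to_pd.items():
        bands = params.transitions.sd_to_death.get(reg, {})
        for band, d in bands.items():
            if e.value + d.value > 1.0:
                v.append(Violation(
                    f"transitions.sd_to_pd.{reg}+sd_to_death.{reg}.{band}",
                    f"row sum {e.value + d.value:.3f} exceeds 1"))

    for name in ("sd_on_iv", "sd_on_oral", "sd_off", "pd_on_iv", "pd_off"):
        u = getattr(params.utilities, name).value
        if not (0.0 <= u <= 1.0):
            v.append(Violation(f"utilities.{name}", "utility must be in [0, 1]"))

    for agent, d in params.unit_costs.drug_prices.items():
        if d.usd_per_package < 0:
            v.append(Violation(f"unit_costs.drug_prices.{agent}",
                               "price must be non-negative"))
        if not d.mg_per_package > 0:
            v.append(Violation(f"unit_costs.drug_prices.{agent}",
                               "mg per package must be positive"))
    for m, e in params.unit_costs.administration.items():
        if e.value < 0:
            v.append(Violation(f"unit_costs.administration.{m}",
                               "cost must be non-negative"))
    for key in ("food", "transportation"):
        if getattr(params.unit_costs, key).value < 0:
            v.append(Violation(f"unit_costs.{key}", "cost must be non-negative"))

    for key, e in params.care_costs.costs.items():
        if e.value < 0:
            v.append(Violation(f"care_costs.{key}", "cost must be non-negative"))

    for reg, n in params.visits.per_course.items():
        if n < 0 or int(n) != n:
            v.append(Violation(f"visits.per_course.{reg}",
                               "visit count must be a non-negative integer"))
    for key, n in params.visits.state_year.items():
        if n < 0:
            v.append(Violation(f"visits.state_year.{key}",
                               "visit rate must be non-negative"))

    for name, reg in params.regimens.items():
        for i, rule in enumerate(reg.dose_rules):
            if rule.dose_mg_per_m2 < 0:
                v.append(Violation(f"regimens.{name}.dose_rules[{i}].dose",
                                   "dose must be non-negative"))
            if rule.days_per_cycle < 1:
                v.append(Violation(f"regimens.{name}.dose_rules[{i}].days",
                                   "days per cycle must be at least 1"))
            if rule.cycles_per_course < 0:
                v.append(Violation(f"regimens.{name}.dose_rules[{i}].cycles",
                                   "cycles per course must be non-negative"))
        if reg.admin_modality not in ADMIN_MODALITIES:
            v.append(Violation(f"regimens.{name}.admin_modality",
                               f"unknown modality {reg.admin_modality!r}"))
        if reg.care_setting not in ("OPD", "IPD"):
            v.append(Violation(f"regimens.{name}.care_setting",
                               f"unknown care setting {reg.care_setting!r}"))

    b = params.bia
    if not b.population > 0:
        v.append(Violation("bia.population", "population must be positive"))
    for fname in ("accessibility", "population_growth"):
        x = getattr(b, fname)
        if not (0.0 <= x <= 1.0):
            v.append(Violation(f"bia.{fname}", "must be in [0, 1]"))
    if b.incidence_per_100k < 0:
        v.append(Violation("bia.incidence_per_100k", "must be non-negative"))

    return v
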