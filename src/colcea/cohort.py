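"""Three-state Markov cohort engine with tunnel compartments.

The model follows a cohort of newly diagnosed stage III colorectal cancer
patients, all starting adjuvant (first-line) chemotherapy at the cohort start
age.  Three health states — stable disease (SD), progressive disease (PD) and
death — are expanded into tunnel compartments so transition probabilities can
depend on time in state: SD is split by years since diagnosis (1..4, then an
open 5+ band) and PD by years since progression (1..3, then 4+).  Movement is
strictly forward: SD(y) -> {SD(y+1), PD(1), DEAD}, PD(y) -> {PD(y+1), DEAD},
DEAD absorbs.

Death from any cause combines the regimen- and band-specific disease
mortality with the age-specific background probability from a life table
(independent competing risks by default).  If a combined row would exceed
unity, death takes priority and the progression probability is truncated;
published base-case values never trigger this.

Reward conventions (switchable via :class:`EngineOptions`).  The defaults
are the conventions that reproduce the published lifetime totals; each knob
also offers the textbook alternative:

* Life years and annual care costs accrue to cohort members present at the
  *start* of a cycle (``credit="begin"``): entering a year earns that year.
  ``"end"`` restricts credit to members who survive the cycle, and
  ``"half"`` is the half-cycle correction (the mean of the two).
* QALYs accrue to members who *complete* a cycle (``qaly_credit="end"``).
* In the first SD year the adjuvant course occupies the first half of the
  year and only the post-treatment half carries a utility weight
  (``year1_utility="off_half"``: 0.5 x u(SD, off treatment)).  The
  ``"blend"`` alternative credits the treated half at the on-treatment
  utility as well.  The first PD year always blends on- and off-treatment
  utility with the treated fraction.
* Chemotherapy courses are charged on entry to the treated year — the whole
  cohort is charged the first-line course in cycle 1, and each season's new
  PD entrants are charged the second-line course in their first PD year —
  regardless of survival through that year (drugs are delivered up front).
* Discounting multiplies cycle t rewards by (1 + r)^-(t-1): the first year
  is undiscounted, future years are discounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .costing import course_cost
from .mortality import LifeTable, annual_background_q, combine_mortality
from .parameters import (
    FIRST_LINE_REGIMENS,
    PD_BANDS,
    SD_BANDS,
    SECOND_LINE_REGIMENS,
    ModelParameters,
)

__all__ = [
    "StrategyDefinition",
    "STRATEGIES",
    "strategy_by_name",
    "EngineOptions",
    "CohortTrace",
    "StrategyResult",
    "N_COMPARTMENTS",
    "IDX_SD",
    "IDX_PD",
    "IDX_DEAD",
    "compartment_labels",
    "transition_step",
    "cycle_rewards",
    "run_cohort",
    "accumulate_outcomes",
    "run_strategy",
]

# Compartment layout: SD years 1..5+ | PD years 1..4+ | DEAD
N_SD = len(SD_BANDS)           # 5
N_PD = len(PD_BANDS)           # 4
N_COMPARTMENTS = N_SD + N_PD + 1
IDX_SD = tuple(range(N_SD))
IDX_PD = tuple(range(N_SD, N_SD + N_PD))
IDX_DEAD = N_SD + N_PD


def compartment_labels() -> list[str]:
    return ([f"SD{b}" for b in SD_BANDS] + [f"PD{b}" for b in PD_BANDS]
            + ["DEAD"])


@dataclass(frozen=True)
class StrategyDefinition:
    """A first-line (adjuvant, SD phase) / second-line (PD phase) pairing."""

    name: str
    first_line: str
    second_line: str

    def __post_init__(self) -> None:
        if self.first_line not in FIRST_LINE_REGIMENS:
            raise ValueError(f"{self.first_line!r} is not a first-line regimen")
        if self.second_line not in SECOND_LINE_REGIMENS:
            raise ValueError(f"{self.second_line!r} is not a second-line regimen")


#: The eight compared strategies, in the published presentation order.
STRATEGIES: tuple[StrategyDefinition, ...] = (
    StrategyDefinition("5-FU/LV->FOLFIRI", "5-FU/LV", "FOLFIRI"),
    StrategyDefinition("5-FU/LV->FOLFOX", "5-FU/LV", "FOLFOX"),
    StrategyDefinition("5-FU/LV->CAPOX", "5-FU/LV", "CAPOX"),
    StrategyDefinition("capecitabine->FOLFIRI", "capecitabine", "FOLFIRI"),
    StrategyDefinition("capecitabine->FOLFOX", "capecitabine", "FOLFOX"),
    StrategyDefinition("capecitabine->CAPOX", "capecitabine", "CAPOX"),
    StrategyDefinition("FOLFOX->FOLFIRI", "FOLFOX", "FOLFIRI"),
    StrategyDefinition("CAPOX->FOLFIRI", "CAPOX", "FOLFIRI"),
)


def strategy_by_name(name: str) -> StrategyDefinition:
    for s in STRATEGIES:
        if s.name == name:
            return s
    raise KeyError(f"unknown strategy {name!r}; known: "
                   + ", ".join(s.name for s in STRATEGIES))


@dataclass(frozen=True)
class EngineOptions:
    """Switchable engine conventions (defaults are the package's base case)."""

    mortality_policy: str = "product"   # see mortality.combine_mortality
    credit: str = "begin"               # LY + care-cost credit: begin|end|half
    qaly_credit: str = "end"            # QALY credit: begin|end|half
    year1_utility: str = "off_half"     # SD year-1 utility: off_half|blend
    discount_from_first_cycle: bool = False  # discount cycle 1 by 1/(1+r)
    stop_alive_fraction: float = 1e-8

    def __post_init__(self) -> None:
        if self.credit not in ("begin", "end", "half"):
            raise ValueError(f"unknown credit rule {self.credit!r}")
        if self.qaly_credit not in ("begin", "end", "half"):
            raise ValueError(f"unknown QALY credit rule {self.qaly_credit!r}")
        if self.year1_utility not in ("off_half", "blend"):
            raise ValueError(f"unknown year-1 utility {self.year1_utility!r}")


@dataclass
class CycleTables:
    """Per-compartment probabilities and rewards for one model cycle."""

    p_death: np.ndarray       # (9,) alive compartments
    p_progress: np.ndarray    # (9,) zero outside SD
    utility: np.ndarray       # (9,)
    care_cost: np.ndarray     # (9,) annual care + visit non-medical, survivors
    course_drug: np.ndarray   # (9,) charged on entry occupancy
    course_admin: np.ndarray
    course_nonmed: np.ndarray


def _configuration_error(strategy: StrategyDefinition, kind: str,
                         regimen: str) -> KeyError:
    return KeyError(f"strategy {strategy.name!r}: no {kind} probabilities for "
                    f"regimen {regimen!r}")


def _build_cycle_tables(strategy: StrategyDefinition, params: ModelParameters,
                        life_table: LifeTable, cycle_index: int,
                        options: EngineOptions) -> CycleTables:
    s = params.settings
    age = s.start_age + (cycle_index - 1) * s.cycle_length
    q_bg = annual_background_q(life_table, age)

    first = params.regimens[strategy.first_line]
    second = params.regimens[strategy.second_line]
    try:
        sd_pd = params.transitions.sd_to_pd[strategy.first_line].value
        sd_death = params.transitions.sd_to_death[strategy.first_line]
    except KeyError:
        raise _configuration_error(strategy, "SD", strategy.first_line) from None
    try:
        pd_death = params.transitions.pd_to_death[strategy.second_line]
    except KeyError:
        raise _configuration_error(strategy, "PD", strategy.second_line) from None

    p_death = np.zeros(N_SD + N_PD)
    p_prog = np.zeros(N_SD + N_PD)
    for y, band in enumerate(SD_BANDS):
        q = combine_mortality(sd_death[band].value, q_bg,
                              policy=options.mortality_policy)
        p_death[y] = q
        p_prog[y] = min(sd_pd, 1.0 - q)  # death takes priority in a full row
    for y, band in enumerate(PD_BANDS):
        p_death[N_SD + y] = combine_mortality(pd_death[band].value, q_bg,
                                              policy=options.mortality_policy)

    u = params.utilities
    tf = s.treated_fraction_of_first_cycle
    u_sd_on = (u.sd_on_oral.value if first.is_oral_backbone else u.sd_on_iv.value)
    u_pd_on = u.pd_on_iv.value  # no published utility for oral PD treatment
    utility = np.empty(N_SD + N_PD)
    if options.year1_utility == "off_half":
        # only the post-treatment half of the first SD year is quality-weighted
        utility[IDX_SD[0]] = (1.0 - tf) * u.sd_off.value
    else:
        utility[IDX_SD[0]] = tf * u_sd_on + (1.0 - tf) * u.sd_off.value
    utility[IDX_SD[1]:N_SD] = u.sd_off.value
    utility[IDX_PD[0]] = tf * u_pd_on + (1.0 - tf) * u.pd_off.value
    utility[IDX_PD[1]:] = u.pd_off.value

    cc = params.care_costs
    per_visit = params.unit_costs.nonmedical_per_visit
    vs = params.visits.state_year
    sd1_setting = "ipd" if first.care_setting == "IPD" else "opd"
    pd1_setting = "ipd" if second.care_setting == "IPD" else "opd"
    care = np.empty(N_SD + N_PD)
    care[IDX_SD[0]] = (cc[f"sd_year1_{sd1_setting}"].value
                       + vs["sd_year1_off"] * per_visit)
    care[IDX_SD[1]] = cc["sd_year2"].value + vs["sd_year2"] * per_visit
    care[IDX_SD[2]:N_SD] = (cc["sd_year3plus"].value
                            + vs["sd_year3plus"] * per_visit)
    care[IDX_PD[0]] = (cc[f"pd_year1_{pd1_setting}"].value
                       + vs["pd_year1_off"] * per_visit)
    care[IDX_PD[1]] = cc["pd_year2"].value + vs["pd_year2"] * per_visit
    care[IDX_PD[2]:] = cc["pd_year3plus"].value + vs["pd_year3plus"] * per_visit

    course_drug = np.zeros(N_SD + N_PD)
    course_admin = np.zeros(N_SD + N_PD)
    course_nonmed = np.zeros(N_SD + N_PD)
    first_course = course_cost(first, s.bsa, params.unit_costs)
    second_course = course_cost(second, s.bsa, params.unit_costs)
    course_drug[IDX_SD[0]] = first_course.drug
    course_admin[IDX_SD[0]] = first_course.administration
    course_nonmed[IDX_SD[0]] = first_course.nonmedical
    course_drug[IDX_PD[0]] = second_course.drug
    course_admin[IDX_PD[0]] = second_course.administration
    course_nonmed[IDX_PD[0]] = second_course.nonmedical

    return CycleTables(p_death, p_prog, utility, care, course_drug,
                       course_admin, course_nonmed)


def initial_state() -> np.ndarray:
    """Whole cohort newly diagnosed, entering SD year 1."""
    occ = np.zeros(N_COMPARTMENTS)
    occ[IDX_SD[0]] = 1.0
    return occ


def transition_step(state: np.ndarray, strategy: StrategyDefinition,
                    params: ModelParameters, life_table: LifeTable,
                    cycle_index: int,
                    options: EngineOptions = EngineOptions()) -> np.ndarray:
    """Advance the cohort one cycle; occupancy is conserved exactly."""
    t = _build_cycle_tables(strategy, params, life_table, cycle_index, options)
    return _apply_transition(state, t)


def _apply_transition(state: np.ndarray, t: CycleTables) -> np.ndarray:
    out = np.zeros(N_COMPARTMENTS)
    out[IDX_DEAD] = state[IDX_DEAD]
    for y in IDX_SD:
        o = state[y]
        if o == 0.0:
            continue
        out[IDX_DEAD] += o * t.p_death[y]
        out[IDX_PD[0]] += o * t.p_progress[y]
        stay = o * (1.0 - t.p_death[y] - t.p_progress[y])
        out[min(y + 1, IDX_SD[-1])] += stay
    for y in IDX_PD:
        o = state[y]
        if o == 0.0:
            continue
        out[IDX_DEAD] += o * t.p_death[y]
        out[min(y + 1, IDX_PD[-1])] += o * (1.0 - t.p_death[y])
    return out


def cycle_rewards(state_before: np.ndarray, state_after: np.ndarray,
                  strategy: StrategyDefinition, params: ModelParameters,
                  life_table: LifeTable, cycle_index: int,
                  options: EngineOptions = EngineOptions()) -> dict[str, float]:
    """Undiscounted rewards earned in one cycle, plus the discount factor.

    Returns a dict with keys ``ly``, ``qaly``, ``cost`` and the cost
    components ``drug``, ``administration``, ``care``, ``nonmedical``, and
    ``discount`` (the factor applying to this cycle).
    """
    t = _build_cycle_tables(strategy, params, life_table, cycle_index, options)
    alive = state_before[: N_SD + N_PD]
    survivors = alive * (1.0 - t.p_death)

    def _credit(rule: str) -> np.ndarray:
        if rule == "begin":
            return alive
        if rule == "end":
            return survivors
        return 0.5 * (alive + survivors)  # half-cycle correction

    credit = _credit(options.credit)          # LY + annual care costs
    qcredit = _credit(options.qaly_credit)    # QALYs

    ly = float(np.sum(credit))
    qaly = float(np.sum(qcredit * t.utility))
    care = float(np.sum(credit * t.care_cost))
    drug = float(np.sum(alive * t.course_drug))
    admin = float(np.sum(alive * t.course_admin))
    course_nonmed = float(np.sum(alive * t.course_nonmed))
    # care_cost already includes state-year visit non-medical costs; split
    # them out so the reported breakdown separates care from non-medical:
    visit_nonmed = _visit_nonmed_component(credit, params, strategy)
    nonmedical = course_nonmed + visit_nonmed
    other_care = care - visit_nonmed

    r = params.settings.discount_rate
    exponent = cycle_index if options.discount_from_first_cycle else cycle_index - 1
    discount = (1.0 + r) ** (-exponent)
    cost = drug + admin + course_nonmed + care
    return {"ly": ly, "qaly": qaly, "cost": cost, "drug": drug,
            "administration": admin, "care": other_care,
            "nonmedical": nonmedical, "discount": discount}


def _visit_nonmed_component(credit: np.ndarray, params: ModelParameters,
                            strategy: StrategyDefinition) -> float:
    per_visit = params.unit_costs.nonmedical_per_visit
    vs = params.visits.state_year
    rates = np.empty(N_SD + N_PD)
    rates[IDX_SD[0]] = vs["sd_year1_off"]
    rates[IDX_SD[1]] = vs["sd_year2"]
    rates[IDX_SD[2]:N_SD] = vs["sd_year3plus"]
    rates[IDX_PD[0]] = vs["pd_year1_off"]
    rates[IDX_PD[1]] = vs["pd_year2"]
    rates[IDX_PD[2]:] = vs["pd_year3plus"]
    return float(np.sum(credit * rates) * per_visit)


@dataclass
class CohortTrace:
    """Cycle-indexed occupancy and rewards for one strategy run."""

    strategy: StrategyDefinition
    cycles: np.ndarray          # (T,) 1-based cycle index
    ages: np.ndarray            # (T,) attained age during the cycle
    occupancy_before: np.ndarray  # (T, 10)
    occupancy_after: np.ndarray   # (T, 10)
    discount: np.ndarray        # (T,)
    ly: np.ndarray              # (T,) undiscounted
    qaly: np.ndarray
    cost: np.ndarray
    cost_drug: np.ndarray
    cost_admin: np.ndarray
    cost_care: np.ndarray
    cost_nonmed: np.ndarray

    def to_frame(self):
        """Trace as a pandas DataFrame (cycle, age, compartments, rewards)."""
        import pandas as pd

        data = {"cycle": self.cycles, "age": self.ages}
        for i, lbl in enumerate(compartment_labels()):
            data[lbl] = self.occupancy_after[:, i]
        data.update(discount=self.discount, ly=self.ly, qaly=self.qaly,
                    cost=self.cost)
        return pd.DataFrame(data)


@dataclass
class StrategyResult:
    """Lifetime totals for one strategy (discounted and undiscounted)."""

    strategy: str
    cost: float
    ly: float
    qaly: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float
    breakdown: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"strategy": self.strategy, "cost": self.cost, "ly": self.ly,
                "qaly": self.qaly,
                "cost_undiscounted": self.cost_undiscounted,
                "ly_undiscounted": self.ly_undiscounted,
                "qaly_undiscounted": self.qaly_undiscounted,
                "breakdown": dict(self.breakdown)}


def run_cohort(strategy: StrategyDefinition, params: ModelParameters,
               life_table: LifeTable,
               options: EngineOptions = EngineOptions()) -> CohortTrace:
    """Follow the cohort from the start age until death or the horizon age."""
    s = params.settings
    rows: list[dict] = []
    state = initial_state()
    cycle = 0
    while True:
        cycle += 1
        age = s.start_age + (cycle - 1) * s.cycle_length
        if age >= s.horizon_age:
            break
        alive = 1.0 - state[IDX_DEAD]
        if alive < options.stop_alive_fraction:
            break
        t = _build_cycle_tables(strategy, params, life_table, cycle, options)
        after = _apply_transition(state, t)
        rew = cycle_rewards(state, after, strategy, params, life_table, cycle,
                            options)
        rows.append({"cycle": cycle, "age": age, "before": state,
                     "after": after, **rew})
        state = after

    T = len(rows)
    trace = CohortTrace(
        strategy=strategy,
        cycles=np.array([r["cycle"] for r in rows], dtype=int),
        ages=np.array([r["age"] for r in rows]),
        occupancy_before=np.vstack([r["before"] for r in rows]) if T else
        np.zeros((0, N_COMPARTMENTS)),
        occupancy_after=np.vstack([r["after"] for r in rows]) if T else
        np.zeros((0, N_COMPARTMENTS)),
        discount=np.array([r["discount"] for r in rows]),
        ly=np.array([r["ly"] for r in rows]),
        qaly=np.array([r["qaly"] for r in rows]),
        cost=np.array([r["cost"] for r in rows]),
        cost_drug=np.array([r["drug"] for r in rows]),
        cost_admin=np.array([r["administration"] for r in rows]),
        cost_care=np.array([r["care"] for r in rows]),
        cost_nonmed=np.array([r["nonmedical"] for r in rows]),
    )
    return trace


def accumulate_outcomes(trace: CohortTrace,
                        params: ModelParameters) -> StrategyResult:
    """Sum a trace into lifetime totals, discounted and undiscounted."""
    d = trace.discount
    return StrategyResult(
        strategy=trace.strategy.name,
        cost=float(np.sum(trace.cost * d)),
        ly=float(np.sum(trace.ly * d)),
        qaly=float(np.sum(trace.qaly * d)),
        cost_undiscounted=float(np.sum(trace.cost)),
        ly_undiscounted=float(np.sum(trace.ly)),
        qaly_undiscounted=float(np.sum(trace.qaly)),
        breakdown={
            "drug": float(np.sum(trace.cost_drug * d)),
            "administration": float(np.sum(trace.cost_admin * d)),
            "care": float(np.sum(trace.cost_care * d)),
            "nonmedical": float(np.sum(trace.cost_nonmed * d)),
        },
    )


def run_strategy(strategy: StrategyDefinition | str, params: ModelParameters,
                 life_table: LifeTable,
                 options: EngineOptions = EngineOptions()) -> StrategyResult:
    """Convenience: run one strategy and accumulate its lifetime totals."""
    if isinstance(strategy, str):
        strategy = strategy_by_name(strategy)
    return accumulate_outcomes(run_cohort(strategy, params, life_table, options),
                               params)
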