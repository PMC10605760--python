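"""Five-year payer-perspective budget impact projection.

Each calendar year a new incident cohort of stage III patients starts
first-line adjuvant treatment: national population (growing at a fixed
annual rate) x incidence rate x treatment accessibility.  Patients from
earlier incident cohorts who are still in stable disease progress at their
first-line regimen's annual relapse probability — SD survival is propagated
by the same cohort engine that drives the cost-utility analysis, so both
analyses share one disease model — and the accessible fraction of relapsers
starts second-line treatment in the year of relapse.

The payer perspective counts drug acquisition and administration costs only
(no care, food or transportation costs), undiscounted, as is conventional
for budget impact.  Patient counts stay fractional (expected-value
budgeting); rounding belongs to presentation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    IDX_PD,
    EngineOptions,
    StrategyDefinition,
    run_cohort,
)
from .costing import course_cost
from .mortality import LifeTable
from .parameters import BIAInputs, ModelParameters

__all__ = [
    "incident_treated",
    "relapse_treated",
    "annual_budget",
    "five_year_table",
]


def incident_treated(year: int, inputs: BIAInputs) -> float:
    """Newly treated first-line patients in a calendar year (fractional).

    population x (1+growth)^(year-1) x incidence x accessibility.
    """
    if year < 1 or year > inputs.horizon_years:
        raise ValueError(f"year {year} outside BIA horizon")
    pop = inputs.population * (1.0 + inputs.population_growth) ** (year - 1)
    return pop * inputs.incidence_per_100k / 100_000.0 * inputs.accessibility


def _pd_inflow_per_cycle(strategy: StrategyDefinition, params: ModelParameters,
                         life_table: LifeTable,
                         options: EngineOptions) -> np.ndarray:
    """Fraction of an incident cohort entering PD during each model cycle."""
    trace = run_cohort(strategy, params, life_table, options)
    # PD year-1 occupancy after a cycle's transition is exactly that cycle's
    # new inflow (the compartment holds first-year entrants only).
    return trace.occupancy_after[:, IDX_PD[0]]


def relapse_treated(year: int, strategy: StrategyDefinition,
                    inputs: BIAInputs, params: ModelParameters,
                    life_table: LifeTable,
                    options: EngineOptions = EngineOptions()) -> float:
    """Second-line patients starting treatment in a calendar year.

    Sums over earlier incident cohorts the fraction progressing in this
    calendar year, times accessibility.  Year 1 has no prior cohort and
    therefore no second-line inflow.
    """
    if year < 1 or year > inputs.horizon_years:
        raise ValueError(f"year {year} outside BIA horizon")
    inflow = _pd_inflow_per_cycle(strategy, params, life_table, options)
    total = 0.0
    for j in range(1, year):            # cohort treated in calendar year j
        k = year - j + 1                # that cohort's model cycle this year
        if k - 1 < len(inflow):
            total += incident_treated(j, inputs) * inflow[k - 1]
    return total * inputs.accessibility


def annual_budget(strategy: StrategyDefinition, year: int, inputs: BIAInputs,
                  params: ModelParameters, life_table: LifeTable,
                  options: EngineOptions = EngineOptions()) -> float:
    """Payer budget (USD) for one strategy in one calendar year."""
    bsa = params.settings.bsa
    uc = params.unit_costs
    first = course_cost(params.regimens[strategy.first_line], bsa, uc).payer
    second = course_cost(params.regimens[strategy.second_line], bsa, uc).payer
    return (incident_treated(year, inputs) * first
            + relapse_treated(year, strategy, inputs, params, life_table,
                              options) * second)


def five_year_table(strategies: list[StrategyDefinition],
                    params: ModelParameters, life_table: LifeTable,
                    inputs: BIAInputs | None = None,
                    options: EngineOptions = EngineOptions()) -> pd.DataFrame:
    """Budget table: one row per strategy, yearly columns, total and mean."""
    if inputs is None:
        inputs = params.bia
    years = list(range(1, inputs.horizon_years + 1))
    records = []
    for strat in strategies:
        yearly = [annual_budget(strat, y, inputs, params, life_table, options)
                  for y in years]
        records.append(
            {"strategy": strat.name,
             **{f"year{y}": v for y, v in zip(years, yearly)},
             "total": float(np.sum(yearly)),
             "per_year": float(np.mean(yearly))})
    return pd.DataFrame.from_records(records).set_index("strategy")
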