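"""Synthetic inputs and an individual-level microsimulation oracle.

The registry behind the published transition probabilities is not publicly
deposited, so testing needs three stand-ins, all generated here:

* :func:`random_parameters` — valid random parameter bundles obtained by
  jittering the base case multiplicatively within per-class bounds, with
  row-sum feasibility enforced, so every generated bundle passes
  :func:`colcea.parameters.validate`;
* :func:`stylized_life_table` — a Gompertz mortality curve
  q(age) = min(1, A e^(B age)), a plausible adult-mortality shape used by
  every test that does not target published numbers;
* :func:`microsimulate` — n individual patient trajectories drawn with the
  exact per-cycle transition probabilities and reward conventions of the
  cohort engine (the two share one cycle-table construction), giving an
  independent Monte-Carlo estimate of the cohort expectations.  Agreement
  within sampling error validates the deterministic engine; divergence can
  only reveal an engine bug, not a re-specification drift.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .cohort import (
    IDX_DEAD,
    IDX_PD,
    IDX_SD,
    N_PD,
    N_SD,
    EngineOptions,
    StrategyDefinition,
    _build_cycle_tables,
)
from .mortality import LifeTable
from .parameters import ModelParameters, load_basecase
from .sensitivity import (
    CLASS_COST,
    CLASS_PROBABILITY,
    CLASS_UTILITY,
    get_param,
    iter_uncertain_parameters,
    set_param,
)

__all__ = [
    "SyntheticConfig",
    "random_parameters",
    "stylized_life_table",
    "MicrosimResult",
    "microsimulate",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Bounds and seeds for synthetic input generation.

    Jitter bounds are multiplicative factors applied to the base-case value
    of each parameter class; collapsing a bound pair to (1, 1) reproduces
    the base case exactly.
    """

    seed: int = 0
    prob_jitter: tuple[float, float] = (0.7, 1.3)
    utility_jitter: tuple[float, float] = (0.85, 1.15)
    cost_jitter: tuple[float, float] = (0.6, 1.4)
    gompertz_a: float = 1e-4
    gompertz_b: float = 0.085

    def __post_init__(self) -> None:
        for name in ("prob_jitter", "utility_jitter", "cost_jitter"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} bounds must satisfy 0 <= low <= high")
        if self.gompertz_a <= 0 or self.gompertz_b < 0:
            raise ValueError("Gompertz coefficients need A > 0, B >= 0")


def random_parameters(config: SyntheticConfig,
                      base: ModelParameters | None = None) -> ModelParameters:
    """A valid random parameter bundle jittered around the base case."""
    params = copy.deepcopy(base) if base is not None else load_basecase()
    rng = np.random.default_rng(config.seed)
    jitter = {CLASS_PROBABILITY: config.prob_jitter,
              CLASS_UTILITY: config.utility_jitter,
              CLASS_COST: config.cost_jitter}
    for path, cls in iter_uncertain_parameters(params):
        lo, hi = jitter[cls]
        value = get_param(params, path) * rng.uniform(lo, hi)
        if cls in (CLASS_PROBABILITY, CLASS_UTILITY):
            value = min(max(value, 0.0), 1.0)
        set_param(params, path, value)
    # keep SD rows feasible: progression is truncated so that in every band
    # sd_to_pd + sd_to_death <= 1
    for reg, e in params.transitions.sd_to_pd.items():
        bands = params.transitions.sd_to_death.get(reg, {})
        if bands:
            max_death = max(b.value for b in bands.values())
            e.value = min(e.value, 1.0 - max_death)
    return params


def stylized_life_table(A: float = 1e-4, B: float = 0.085,
                        max_age: int = 110) -> LifeTable:
    """Gompertz life table q(age) = min(1, A e^(B age)) on ages 0..max_age."""
    if A <= 0:
        raise ValueError("Gompertz A must be positive")
    ages = np.arange(0, max_age + 1, dtype=float)
    q = np.minimum(1.0, A * np.exp(B * ages))
    return LifeTable(ages, q, max_age=float(max_age))


@dataclass(frozen=True)
class MicrosimResult:
    n: int
    mean_cost: float
    mean_ly: float
    mean_qaly: float
    se_cost: float
    se_ly: float
    se_qaly: float


def _credit_weights(rule: str) -> tuple[float, float]:
    """(survivor, in-cycle death) reward weights for a credit rule."""
    return {"begin": (1.0, 1.0), "end": (1.0, 0.0), "half": (1.0, 0.5)}[rule]


def microsimulate(strategy: StrategyDefinition, params: ModelParameters,
                  life_table: LifeTable, n: int, seed: int,
                  options: EngineOptions = EngineOptions()) -> MicrosimResult:
    """Simulate n individual trajectories; return reward means and SEs.

    Transitions and rewards use the cohort engine's own per-cycle tables, so
    any systematic disagreement between these means and the cohort totals
    indicates an engine defect rather than a modelling difference.
    """
    if n < 1:
        raise ValueError("need at least one simulated patient")
    rng = np.random.default_rng(seed)
    s = params.settings
    w_ly, w_ly_d = _credit_weights(options.credit)
    w_q, w_q_d = _credit_weights(options.qaly_credit)

    comp = np.zeros(n, dtype=np.int64)  # everyone starts in SD year 1
    cost = np.zeros(n)
    ly = np.zeros(n)
    qaly = np.zeros(n)

    cycle = 0
    while True:
        cycle += 1
        age = s.start_age + (cycle - 1) * s.cycle_length
        if age >= s.horizon_age:
            break
        alive = comp != IDX_DEAD
        if not alive.any():
            break
        t = _build_cycle_tables(strategy, params, life_table, cycle, options)
        r = params.settings.discount_rate
        exponent = (cycle if options.discount_from_first_cycle else cycle - 1)
        d = (1.0 + r) ** (-exponent)

        c = comp[alive]
        # courses and annual care are charged on entering the cycle
        entry_cost = (t.course_drug[c] + t.course_admin[c]
                      + t.course_nonmed[c])
        u = rng.random(c.size)
        dies = u < t.p_death[c]
        progresses = (~dies) & (u < t.p_death[c] + t.p_progress[c])

        surv_w_ly = np.where(dies, w_ly_d, w_ly)
        surv_w_q = np.where(dies, w_q_d, w_q)
        cost[alive] += d * (entry_cost + surv_w_ly * t.care_cost[c])
        ly[alive] += d * surv_w_ly
        qaly[alive] += d * surv_w_q * t.utility[c]

        nxt = c.copy()
        in_sd = c < N_SD
        nxt[in_sd] = np.minimum(c[in_sd] + 1, IDX_SD[-1])
        in_pd = (c >= N_SD) & (c < N_SD + N_PD)
        nxt[in_pd] = np.minimum(c[in_pd] + 1, IDX_PD[-1])
        nxt[progresses] = IDX_PD[0]
        nxt[dies] = IDX_DEAD
        comp[alive] = nxt

    def se(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")

    return MicrosimResult(n, float(cost.mean()), float(ly.mean()),
                          float(qaly.mean()), se(cost), se(ly), se(qaly))
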