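"""One-way and probabilistic sensitivity analyses.

One-way analysis (tornado): each input is moved to its low and high bound —
95% confidence limits where a standard error was published, otherwise ±25%
of the base value (probabilities and utilities clamped to [0, 1]) — and the
ICER of an intervention/comparator strategy pair is recomputed with all
other inputs at base.  Entries are ranked by the absolute ICER span.

Probabilistic analysis: every uncertain input is drawn independently each
iteration — beta for probabilities and utilities, gamma for costs, both
parameterised by method of moments from the mean and standard error.  Inputs
published without a standard error receive an imputed one: 25%/1.96 of the
mean for costs (so the implied 95% interval matches the ±25% one-way
convention) and 10% of the mean for probabilities.  Both fractions are
configurable.  Structural settings (discount rate, ages, visit counts) are
never sampled.  Each iteration runs both strategies of the pair and records
the incremental cost and QALY pair; the cost-effectiveness acceptability
curve is the fraction of iterations with positive net monetary benefit
across a willingness-to-pay grid.

Parameters are addressed by dotted paths, e.g. ``transitions.sd_to_pd.CAPOX``
or ``costs.drug.oxaliplatin``; see :func:`iter_uncertain_parameters`.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .cea import incremental
from .cohort import EngineOptions, StrategyDefinition, run_strategy
from .mortality import LifeTable
from .parameters import ModelParameters

__all__ = [
    "RangeSpec",
    "TornadoEntry",
    "PSAConfig",
    "PSASampleSet",
    "beta_moments",
    "gamma_moments",
    "get_param",
    "set_param",
    "iter_uncertain_parameters",
    "default_ranges",
    "owsa",
    "draw_psa_params",
    "run_psa",
    "ceac",
    "prob_cost_effective",
]

log = logging.getLogger(__name__)

SE_FLOOR = 1e-6

CLASS_PROBABILITY = "probability"
CLASS_UTILITY = "utility"
CLASS_COST = "cost"


# ---------------------------------------------------------------------------
# Distribution moment matching


def beta_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta shape parameters matching a mean and standard error.

    nu = mean(1-mean)/se^2 - 1; alpha = mean nu; beta = (1-mean) nu.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("beta mean must lie strictly inside (0, 1)")
    if se < SE_FLOOR:
        raise ValueError(f"standard error below floor {SE_FLOOR}")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: se^2={se*se:.4g} >= "
            f"mean(1-mean)={mean*(1-mean):.4g}")
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma (shape, scale) matching a mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma moments need positive mean and se")
    return mean * mean / (se * se), se * se / mean


# ---------------------------------------------------------------------------
# Parameter addressing


def _resolve(params: ModelParameters, path: str):
    """Return (container, key, kind) for a dotted parameter path."""
    parts = path.split(".")
    head = parts[0]
    if head == "transitions":
        _, table, *rest = parts
        if table == "sd_to_pd":
            return params.transitions.sd_to_pd, rest[0], "estimate"
        if table == "sd_to_death":
            reg, band = rest
            return params.transitions.sd_to_death[reg], band, "estimate"
        if table == "pd_to_death":
            reg, band = rest
            return params.transitions.pd_to_death[reg], band, "estimate"
    elif head == "utilities":
        return params.utilities, parts[1], "attr_estimate"
    elif head == "costs":
        kind = parts[1]
        if kind == "drug":
            return params.unit_costs.drug_prices, parts[2], "drug_price"
        if kind == "administration":
            return params.unit_costs.administration, parts[2], "estimate"
        if kind == "care":
            return params.care_costs.costs, parts[2], "estimate"
        if kind in ("food", "transportation"):
            return params.unit_costs, kind, "attr_estimate"
    raise KeyError(f"unknown parameter path {path!r}")


def get_param(params: ModelParameters, path: str) -> float:
    container, key, kind = _resolve(params, path)
    if kind == "estimate":
        return container[key].value
    if kind == "attr_estimate":
        return getattr(container, key).value
    return container[key].usd_per_package  # drug_price


def get_param_se(params: ModelParameters, path: str) -> float | None:
    container, key, kind = _resolve(params, path)
    if kind == "estimate":
        return container[key].se
    if kind == "attr_estimate":
        return getattr(container, key).se
    return container[key].se


def set_param(params: ModelParameters, path: str, value: float) -> None:
    container, key, kind = _resolve(params, path)
    if kind == "estimate":
        container[key].value = value
    elif kind == "attr_estimate":
        getattr(container, key).value = value
    else:
        container[key].usd_per_package = value


def iter_uncertain_parameters(
        params: ModelParameters,
        regimens: set[str] | None = None) -> list[tuple[str, str]]:
    """All (path, class) pairs subject to uncertainty analysis.

    ``regimens`` restricts transition probabilities to the given regimens
    (utilities and costs are shared across strategies and always included).
    """
    out: list[tuple[str, str]] = []

    def want(reg: str) -> bool:
        return regimens is None or reg in regimens

    for reg in params.transitions.sd_to_pd:
        if want(reg):
            out.append((f"transitions.sd_to_pd.{reg}", CLASS_PROBABILITY))
    for reg, bands in params.transitions.sd_to_death.items():
        if want(reg):
            out.extend((f"transitions.sd_to_death.{reg}.{b}", CLASS_PROBABILITY)
                       for b in bands)
    for reg, bands in params.transitions.pd_to_death.items():
        if want(reg):
            out.extend((f"transitions.pd_to_death.{reg}.{b}", CLASS_PROBABILITY)
                       for b in bands)
    out.extend((f"utilities.{name}", CLASS_UTILITY)
               for name in ("sd_on_iv", "sd_on_oral", "sd_off",
                            "pd_on_iv", "pd_off"))
    out.extend((f"costs.drug.{agent}", CLASS_COST)
               for agent in params.unit_costs.drug_prices)
    out.extend((f"costs.administration.{m}", CLASS_COST)
               for m in params.unit_costs.administration
               if params.unit_costs.administration[m].value > 0)
    out.extend((f"costs.care.{k}", CLASS_COST) for k in params.care_costs.costs)
    out.append(("costs.food", CLASS_COST))
    out.append(("costs.transportation", CLASS_COST))
    return out


# ---------------------------------------------------------------------------
# One-way sensitivity analysis


@dataclass(frozen=True)
class RangeSpec:
    path: str
    low: float
    high: float
    basis: str  # "95ci" | "pm25" | "explicit"


@dataclass(frozen=True)
class TornadoEntry:
    path: str
    icer_low: float
    icer_high: float
    failed: bool = False

    @property
    def span(self) -> float:
        if self.failed or np.isnan(self.icer_low) or np.isnan(self.icer_high):
            return 0.0
        return abs(self.icer_high - self.icer_low)


def default_ranges(params: ModelParameters,
                   regimens: set[str] | None = None) -> list[RangeSpec]:
    """One-way ranges: 95% CI where a standard error was published (clinical
    effects and utilities), ±25% of the base value otherwise."""
    specs = []
    for path, cls in iter_uncertain_parameters(params, regimens):
        base = get_param(params, path)
        se = get_param_se(params, path)
        if cls in (CLASS_PROBABILITY, CLASS_UTILITY) and se is not None:
            low, high = base - 1.96 * se, base + 1.96 * se
            basis = "95ci"
        else:
            low, high = 0.75 * base, 1.25 * base
            basis = "pm25"
        if cls in (CLASS_PROBABILITY, CLASS_UTILITY):
            low, high = max(low, 0.0), min(high, 1.0)
        else:
            low = max(low, 0.0)
        specs.append(RangeSpec(path, low, high, basis))
    return specs


def _pair_icer(intervention: StrategyDefinition, comparator: StrategyDefinition,
               params: ModelParameters, life_table: LifeTable,
               options: EngineOptions) -> float:
    a = run_strategy(intervention, params, life_table, options)
    b = run_strategy(comparator, params, life_table, options)
    inc = incremental(a, b)
    if inc.delta_qaly == 0.0:
        return float("nan")
    return inc.delta_cost / inc.delta_qaly


def owsa(pair: tuple[StrategyDefinition, StrategyDefinition],
         params: ModelParameters, life_table: LifeTable,
         ranges: list[RangeSpec] | None = None, top: int | None = 15,
         options: EngineOptions = EngineOptions()) -> list[TornadoEntry]:
    """Tornado entries for an intervention vs comparator pair.

    Returns entries sorted by descending ICER span, truncated to ``top``
    (pass ``top=None`` for all).  A range that renders the model infeasible
    is recorded as a failed entry, not a global abort.
    """
    intervention, comparator = pair
    if ranges is None:
        involved = {intervention.first_line, intervention.second_line,
                    comparator.first_line, comparator.second_line}
        ranges = default_ranges(params, involved)

    entries = []
    for spec in ranges:
        icers = []
        failed = False
        for bound in (spec.low, spec.high):
            trial = copy.deepcopy(params)
            try:
                set_param(trial, spec.path, bound)
                icers.append(_pair_icer(intervention, comparator, trial,
                                        life_table, options))
            except (ValueError, KeyError) as exc:
                log.warning("one-way bound failed for %s=%g: %s",
                            spec.path, bound, exc)
                icers.append(float("nan"))
                failed = True
        entries.append(TornadoEntry(spec.path, icers[0], icers[1], failed))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries if top is None else entries[:top]


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PSAConfig:
    iterations: int = 1000
    seed: int = 0
    prob_se_frac: float = 0.10          # imputed SE for probabilities
    cost_se_frac: float = 0.25 / 1.96   # imputed SE for costs
    se_scale: float = 1.0               # global SE multiplier (0 -> base case)

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be at least 1")
        if self.se_scale < 0:
            raise ValueError("se_scale must be non-negative")


@dataclass
class PSASampleSet:
    """Paired incremental draws for one strategy pair."""

    intervention: str
    comparator: str
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    config: PSAConfig
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.delta_cost)


def draw_psa_params(params: ModelParameters, config: PSAConfig,
                    rng: np.random.Generator) -> ModelParameters:
    """One Monte-Carlo draw of every uncertain parameter.

    Probabilities and utilities are drawn beta, costs gamma, by method of
    moments.  Parameters whose moments are degenerate or infeasible (e.g. a
    zero probability) are kept at their base value and reported in the log.
    """
    draw = copy.deepcopy(params)
    for path, cls in iter_uncertain_parameters(params):
        mean = get_param(params, path)
        se = get_param_se(params, path)
        try:
            if cls in (CLASS_PROBABILITY, CLASS_UTILITY):
                if se is None:
                    se = config.prob_se_frac * mean
                a, b = beta_moments(mean, se * config.se_scale)
                value = float(rng.beta(a, b))
            else:
                if se is None:
                    se = config.cost_se_frac * mean
                shape, scale = gamma_moments(mean, se * config.se_scale)
                value = float(rng.gamma(shape, scale))
        except ValueError as exc:
            log.debug("PSA: %s kept at base (%s)", path, exc)
            continue
        set_param(draw, path, value)
    return draw


def run_psa(pair: tuple[StrategyDefinition, StrategyDefinition],
            params: ModelParameters, life_table: LifeTable,
            config: PSAConfig = PSAConfig(),
            options: EngineOptions = EngineOptions()) -> PSASampleSet:
    """Monte-Carlo incremental cost/QALY sample for a strategy pair.

    Per-iteration random substreams are derived from (seed, iteration), so
    the sample set is reproducible and independent of execution order.
    """
    intervention, comparator = pair
    dc = np.empty(config.iterations)
    dq = np.empty(config.iterations)
    for i in range(config.iterations):
        rng = np.random.default_rng([config.seed, i])
        draw = draw_psa_params(params, config, rng)
        a = run_strategy(intervention, draw, life_table, options)
        b = run_strategy(comparator, draw, life_table, options)
        inc = incremental(a, b)
        dc[i] = inc.delta_cost
        dq[i] = inc.delta_qaly
    return PSASampleSet(intervention.name, comparator.name, dc, dq, config)


def ceac(samples: PSASampleSet,
         wtp_grid: np.ndarray | list[float]) -> np.ndarray:
    """Fraction of iterations with positive net monetary benefit per WTP."""
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("willingness-to-pay grid must be non-empty")
    if len(samples) == 0:
        raise ValueError("empty PSA sample set")
    nmb = (grid[:, None] * samples.delta_qaly[None, :]
           - samples.delta_cost[None, :])
    return (nmb > 0).mean(axis=1)


def prob_cost_effective(samples: PSASampleSet, wtp: float) -> float:
    """Probability the intervention is cost-effective at one WTP value."""
    return float(ceac(samples, [wtp])[0])
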