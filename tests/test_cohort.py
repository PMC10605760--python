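"""Markov cohort engine: transitions, reward conventions, conservation."""

import copy

import numpy as np
import pytest

from colcea.cohort import (
    IDX_DEAD,
    IDX_PD,
    IDX_SD,
    EngineOptions,
    cycle_rewards,
    initial_state,
    run_cohort,
    run_strategy,
    strategy_by_name,
    transition_step,
    STRATEGIES,
)
from colcea.parameters import SD_BANDS, PD_BANDS
from colcea.synthetic import SyntheticConfig, random_parameters


def _flat_mortality(params, first, second, q_sd, q_pd, sd_to_pd):
    """Give one strategy's regimens constant disease mortality."""
    params.transitions.sd_to_pd[first].value = sd_to_pd
    for band in SD_BANDS:
        params.transitions.sd_to_death[first][band].value = q_sd
    for band in PD_BANDS:
        params.transitions.pd_to_death[second][band].value = q_pd
    return params


class TestTransitionStep:
    def test_dead_state_is_absorbing(self, basecase, thai_lt):
        state = np.zeros(10)
        state[IDX_DEAD] = 1.0
        strat = strategy_by_name("CAPOX->FOLFIRI")
        out = transition_step(state, strat, basecase, thai_lt, cycle_index=1)
        np.testing.assert_array_equal(out, state)

    def test_first_cycle_split_arithmetic(self, params, zero_lt):
        _flat_mortality(params, "CAPOX", "FOLFIRI", q_sd=0.1, q_pd=0.3,
                        sd_to_pd=0.2)
        strat = strategy_by_name("CAPOX->FOLFIRI")
        out = transition_step(initial_state(), strat, params, zero_lt, 1)
        assert out[IDX_SD[1]] == pytest.approx(0.7)
        assert out[IDX_PD[0]] == pytest.approx(0.2)
        assert out[IDX_DEAD] == pytest.approx(0.1)

    def test_zero_hazards_only_advance_tunnel_clock(self, params, zero_lt):
        _flat_mortality(params, "CAPOX", "FOLFIRI", 0.0, 0.0, 0.0)
        strat = strategy_by_name("CAPOX->FOLFIRI")
        out = transition_step(initial_state(), strat, params, zero_lt, 1)
        assert out[IDX_SD[1]] == pytest.approx(1.0)
        assert out.sum() == pytest.approx(1.0)

    def test_death_priority_truncates_progression(self, params, zero_lt):
        """When disease death fills the row, progression is truncated."""
        _flat_mortality(params, "CAPOX", "FOLFIRI", q_sd=0.95, q_pd=0.3,
                        sd_to_pd=0.2)
        strat = strategy_by_name("CAPOX->FOLFIRI")
        out = transition_step(initial_state(), strat, params, zero_lt, 1)
        assert out[IDX_DEAD] == pytest.approx(0.95)
        assert out[IDX_PD[0]] == pytest.approx(0.05)
        assert out.sum() == pytest.approx(1.0, abs=1e-12)


class TestCycleRewards:
    def test_blended_first_year_utility(self, params, zero_lt):
        """With no deaths, the first SD year blends on-oral and off-treatment
        utility at the treated fraction: 0.5 x 0.651 + 0.5 x 0.850."""
        _flat_mortality(params, "capecitabine", "FOLFOX", 0.0, 0.0, 0.0)
        strat = strategy_by_name("capecitabine->FOLFOX")
        opts = EngineOptions(year1_utility="blend")
        state = initial_state()
        after = transition_step(state, strat, params, zero_lt, 1, opts)
        rew = cycle_rewards(state, after, strat, params, zero_lt, 1, opts)
        assert rew["qaly"] == pytest.approx(0.7505)

    def test_off_half_first_year_utility(self, params, zero_lt):
        """Default convention: only the post-treatment half-year counts."""
        _flat_mortality(params, "capecitabine", "FOLFOX", 0.0, 0.0, 0.0)
        strat = strategy_by_name("capecitabine->FOLFOX")
        state = initial_state()
        after = transition_step(state, strat, params, zero_lt, 1)
        rew = cycle_rewards(state, after, strat, params, zero_lt, 1)
        assert rew["qaly"] == pytest.approx(0.5 * 0.850)

    def test_all_dead_earns_nothing(self, basecase, thai_lt):
        state = np.zeros(10)
        state[IDX_DEAD] = 1.0
        strat = strategy_by_name("CAPOX->FOLFIRI")
        rew = cycle_rewards(state, state, strat, basecase, thai_lt, 1)
        assert rew["ly"] == rew["qaly"] == rew["cost"] == 0.0

    def test_zero_discount_rate_means_unit_factor(self, params, zero_lt):
        params.settings.discount_rate = 0.0
        strat = strategy_by_name("CAPOX->FOLFIRI")
        state = initial_state()
        rew = cycle_rewards(state, state, strat, params, zero_lt, 5)
        assert rew["discount"] == 1.0


class TestClosedForms:
    @pytest.mark.parametrize("q", [0.5, 0.2, 0.8])
    def test_constant_hazard_geometric_life_expectancy(self, params, zero_lt,
                                                       q):
        """Constant combined death probability, no progression: undiscounted
        life expectancy has a geometric closed form -- 1/q when entering a
        year earns it, (1-q)/q when a year must be completed."""
        _flat_mortality(params, "CAPOX", "FOLFIRI", q_sd=q, q_pd=0.0,
                        sd_to_pd=0.0)
        params.settings.discount_rate = 0.0
        params.settings.horizon_age = 400.0
        strat = strategy_by_name("CAPOX->FOLFIRI")
        begin = run_strategy(strat, params, zero_lt,
                             EngineOptions(stop_alive_fraction=1e-14))
        assert begin.ly_undiscounted == pytest.approx(1.0 / q, abs=1e-9)
        end = run_strategy(strat, params, zero_lt,
                           EngineOptions(credit="end",
                                         stop_alive_fraction=1e-14))
        assert end.ly_undiscounted == pytest.approx((1.0 - q) / q, abs=1e-9)


class TestTraceInvariants:
    @pytest.mark.parametrize("seed", range(12))
    def test_occupancy_conserved_on_random_parameters(self, stylized_lt, seed):
        p = random_parameters(SyntheticConfig(seed=seed))
        strat = STRATEGIES[seed % len(STRATEGIES)]
        trace = run_cohort(strat, p, stylized_lt)
        np.testing.assert_allclose(trace.occupancy_before.sum(axis=1), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(trace.occupancy_after.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_dead_occupancy_monotone_and_rewards_non_negative(self, basecase,
                                                              thai_lt):
        trace = run_cohort(strategy_by_name("5-FU/LV->FOLFOX"), basecase,
                           thai_lt)
        dead = trace.occupancy_after[:, IDX_DEAD]
        assert np.all(np.diff(dead) >= 0)
        for arr in (trace.ly, trace.qaly, trace.cost):
            assert np.all(arr >= 0)

    def test_cohort_is_followed_until_extinction(self, basecase, thai_lt):
        trace = run_cohort(strategy_by_name("CAPOX->FOLFIRI"), basecase,
                           thai_lt)
        assert trace.occupancy_after[-1, IDX_DEAD] >= 1 - 1e-4

    def test_discounted_totals_below_undiscounted(self, basecase, thai_lt):
        res = run_strategy(strategy_by_name("CAPOX->FOLFIRI"), basecase,
                           thai_lt)
        assert res.cost < res.cost_undiscounted
        assert res.ly < res.ly_undiscounted
        assert res.qaly < res.qaly_undiscounted

    def test_discounting_reduces_totals_vs_zero_rate(self, params, thai_lt):
        strat = strategy_by_name("capecitabine->CAPOX")
        at3 = run_strategy(strat, params, thai_lt)
        params.settings.discount_rate = 0.0
        at0 = run_strategy(strat, params, thai_lt)
        assert at3.qaly < at0.qaly and at3.cost < at0.cost

    def test_breakdown_sums_to_total_cost(self, basecase, thai_lt):
        res = run_strategy(strategy_by_name("FOLFOX->FOLFIRI"), basecase,
                           thai_lt)
        assert sum(res.breakdown.values()) == pytest.approx(res.cost)


class TestMonotoneHarm:
    @pytest.mark.parametrize("path", [
        "transitions.sd_to_pd.CAPOX",
        "transitions.sd_to_death.CAPOX.year2",
        "transitions.pd_to_death.FOLFIRI.year1",
    ])
    def test_raising_any_hazard_never_raises_qalys(self, basecase, thai_lt,
                                                   path):
        from colcea.sensitivity import get_param, set_param
        strat = strategy_by_name("CAPOX->FOLFIRI")
        base = run_strategy(strat, basecase, thai_lt).qaly
        worse = copy.deepcopy(basecase)
        set_param(worse, path, min(1.0, get_param(worse, path) + 0.1))
        assert run_strategy(strat, worse, thai_lt).qaly <= base + 1e-12
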