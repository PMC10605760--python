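"""Moment matching, one-way tornado, and probabilistic sensitivity draws."""

import numpy as np
import pytest

from colcea.cohort import strategy_by_name
from colcea.sensitivity import (
    PSAConfig,
    PSASampleSet,
    RangeSpec,
    beta_moments,
    ceac,
    default_ranges,
    draw_psa_params,
    gamma_moments,
    get_param,
    owsa,
    prob_cost_effective,
    run_psa,
    set_param,
)

PAIR_NAMES = ("CAPOX->FOLFIRI", "5-FU/LV->FOLFOX")


@pytest.fixture(scope="module")
def pair():
    return tuple(strategy_by_name(n) for n in PAIR_NAMES)


class TestMomentMatching:
    def test_beta_from_published_utility(self):
        a, b = beta_moments(0.600, 0.063)
        assert a == pytest.approx(35.68, abs=0.01)
        assert b == pytest.approx(23.79, abs=0.01)
        # analytic mean identity
        assert a / (a + b) == pytest.approx(0.600, abs=1e-9)

    def test_beta_rejects_degenerate_and_infeasible(self):
        with pytest.raises(ValueError, match="floor"):
            beta_moments(0.5, 1e-9)
        with pytest.raises(ValueError, match="infeasible"):
            beta_moments(0.5, 0.6)
        with pytest.raises(ValueError):
            beta_moments(0.0, 0.1)

    @pytest.mark.parametrize("mean,se,shape,scale", [
        (2041, 510.25, 16.0, 127.5625),
        (5, 0.2, 625.0, 0.008),
    ])
    def test_gamma_from_published_costs(self, mean, se, shape, scale):
        got = gamma_moments(mean, se)
        assert got == pytest.approx((shape, scale))
        assert got[0] * got[1] == pytest.approx(mean)

    def test_gamma_rejects_non_positive(self):
        with pytest.raises(ValueError):
            gamma_moments(0, 1)
        with pytest.raises(ValueError):
            gamma_moments(100, 0)


class TestParameterPaths:
    def test_get_set_round_trip(self, params):
        path = "costs.drug.oxaliplatin"
        before = get_param(params, path)
        set_param(params, path, before * 2)
        assert get_param(params, path) == before * 2

    def test_unknown_path_raises(self, basecase):
        with pytest.raises(KeyError):
            get_param(basecase, "costs.hotel.presidential_suite")

    def test_default_ranges_respect_published_se_and_bounds(self, basecase):
        specs = {s.path: s for s in default_ranges(basecase)}
        sd_off = specs["utilities.sd_off"]       # 0.850 (0.100) -> 95% CI
        assert sd_off.basis == "95ci"
        assert sd_off.low == pytest.approx(0.850 - 1.96 * 0.100)
        assert sd_off.high == 1.0                # clamped at the utility cap
        care = specs["costs.care.sd_year2"]      # no SE -> +-25%
        assert care.basis == "pm25"
        assert (care.low, care.high) == (pytest.approx(2041 * 0.75),
                                         pytest.approx(2041 * 1.25))


class TestOWSA:
    def test_empty_ranges_give_empty_tornado(self, basecase, thai_lt, pair):
        assert owsa(pair, basecase, thai_lt, ranges=[]) == []

    def test_zero_width_range_has_zero_span_and_sorts_last(self, basecase,
                                                           thai_lt, pair):
        ranges = [RangeSpec("costs.drug.capecitabine", 1.5, 2.5, "explicit"),
                  RangeSpec("costs.food", 2.0, 2.0, "explicit")]
        entries = owsa(pair, basecase, thai_lt, ranges=ranges, top=None)
        assert entries[-1].path == "costs.food"
        assert entries[-1].span == 0.0
        assert entries[0].span > 0.0

    def test_span_invariant_to_bound_labelling(self, basecase, thai_lt, pair):
        fwd = RangeSpec("costs.drug.capecitabine", 1.5, 2.5, "explicit")
        rev = RangeSpec("costs.drug.capecitabine", 2.5, 1.5, "explicit")
        e_fwd = owsa(pair, basecase, thai_lt, ranges=[fwd])[0]
        e_rev = owsa(pair, basecase, thai_lt, ranges=[rev])[0]
        assert e_fwd.span == pytest.approx(e_rev.span)


class TestPSADraws:
    def test_same_rng_state_reproduces_draw(self, basecase):
        cfg = PSAConfig(seed=5)
        d1 = draw_psa_params(basecase, cfg, np.random.default_rng(42))
        d2 = draw_psa_params(basecase, cfg, np.random.default_rng(42))
        assert d1 == d2

    def test_draws_collapse_to_base_as_se_scale_vanishes(self, basecase):
        cfg = PSAConfig(se_scale=1e-4)
        draw = draw_psa_params(basecase, cfg, np.random.default_rng(3))
        for path in ("transitions.sd_to_pd.CAPOX", "utilities.sd_off",
                     "costs.care.pd_year2", "costs.drug.irinotecan"):
            assert get_param(draw, path) == pytest.approx(
                get_param(basecase, path), rel=1e-3)

    def test_zero_probability_parameter_kept_at_base(self, basecase):
        draw = draw_psa_params(basecase, PSAConfig(),
                               np.random.default_rng(0))
        assert get_param(draw, "transitions.sd_to_death.FOLFOX.year1") == 0.0

    def test_empirical_mean_matches_published_mean(self, basecase):
        """Monte-Carlo mean of a sampled utility stays within 3 standard
        errors of its published mean."""
        n = 600
        draws = np.empty(n)
        for i in range(n):
            rng = np.random.default_rng([9, i])
            draws[i] = get_param(draw_psa_params(basecase, PSAConfig(), rng),
                                 "utilities.sd_on_iv")
        assert abs(draws.mean() - 0.600) < 3 * 0.063 / np.sqrt(n)


@pytest.fixture(scope="module")
def small_sample(basecase, thai_lt, pair):
    return run_psa(pair, basecase, thai_lt, PSAConfig(iterations=40, seed=11))


class TestRunPSAAndCEAC:
    def test_single_iteration_yields_single_pair(self, basecase, thai_lt,
                                                 pair):
        s = run_psa(pair, basecase, thai_lt, PSAConfig(iterations=1, seed=0))
        assert len(s) == 1

    def test_same_seed_reproduces_sample_set(self, basecase, thai_lt, pair,
                                             small_sample):
        again = run_psa(pair, basecase, thai_lt,
                        PSAConfig(iterations=40, seed=11))
        np.testing.assert_array_equal(again.delta_cost,
                                      small_sample.delta_cost)
        np.testing.assert_array_equal(again.delta_qaly,
                                      small_sample.delta_qaly)

    def test_ceac_definition_and_limits(self, small_sample):
        grid = np.array([0.0, 5003.0, 1e9])
        frac = ceac(small_sample, grid)
        assert np.all((0.0 <= frac) & (frac <= 1.0))
        assert frac[0] == np.mean(small_sample.delta_cost < 0)
        if np.all(small_sample.delta_qaly > 0):
            assert frac[-1] == 1.0
            assert np.all(np.diff(frac) >= 0)

    def test_empty_grid_rejected(self, small_sample):
        with pytest.raises(ValueError, match="grid"):
            ceac(small_sample, [])

    def test_prob_cost_effective_matches_ceac_point(self, small_sample):
        assert prob_cost_effective(small_sample, 5003.0) == \
            ceac(small_sample, [5003.0])[0]

    def test_sample_means_approach_deterministic_incrementals(
            self, basecase, thai_lt, pair):
        """As every standard error is scaled towards zero the PSA cloud
        collapses onto the deterministic incremental point."""
        from colcea.cea import incremental
        from colcea.cohort import run_strategy
        det = incremental(run_strategy(pair[0], basecase, thai_lt),
                          run_strategy(pair[1], basecase, thai_lt))
        s = run_psa(pair, basecase, thai_lt,
                    PSAConfig(iterations=20, seed=2, se_scale=0.01))
        assert s.delta_cost.mean() == pytest.approx(det.delta_cost, rel=0.05)
        assert s.delta_qaly.mean() == pytest.approx(det.delta_qaly, rel=0.05)
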