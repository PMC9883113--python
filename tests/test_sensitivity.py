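"""Tornado analysis, PSA distributions and draws, CEAC, threshold search."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rtcea import (
    beta_from_mean_range,
    ceac,
    evaluate_config,
    gamma_from_mean_range,
    one_way_dsa,
    run_psa,
    threshold_search,
)
from rtcea.errors import InfeasibleMomentsError, ValidationError
from rtcea.parameters_io import ParameterSpec
from rtcea.sensitivity import PSASample, dsa_to_dataframe


class TestBetaFromMeanRange:
    def test_moments_match_published_recurrence_utility(self):
        # mean 0.74, range 0.592-0.888 read as a 95% interval
        a, b = beta_from_mean_range(0.74, 0.592, 0.888)
        assert a / (a + b) == pytest.approx(0.74, abs=1e-9)
        sd = math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        assert sd == pytest.approx((0.888 - 0.592) / 3.92, rel=1e-9)

    def test_symmetric_range_gives_equal_shapes(self):
        a, b = beta_from_mean_range(0.5, 0.3, 0.7)
        assert a == pytest.approx(b, rel=1e-12)

    def test_tight_range_concentrates_at_mean(self):
        a, b = beta_from_mean_range(0.5, 0.5 - 1.96e-4, 0.5 + 1.96e-4)
        draws = stats.beta(a, b).rvs(1000, random_state=0)
        assert np.all(np.abs(draws - 0.5) < 0.01)

    def test_infeasible_variance_rejected(self):
        with pytest.raises(InfeasibleMomentsError):
            beta_from_mean_range(0.01, 0.0, 0.999)

    def test_mean_outside_open_interval_rejected(self):
        with pytest.raises(ValidationError):
            beta_from_mean_range(1.0, 0.5, 0.9)


class TestGammaFromMeanRange:
    def test_mean_identity_for_toxicity_cost(self):
        shape, scale = gamma_from_mean_range(960.0, 768.0, 1152.0)
        assert shape * scale == pytest.approx(960.0, abs=1e-9)

    @given(mean=st.floats(1.0, 1e4), half=st.floats(0.05, 0.5))
    def test_variance_identity(self, mean, half):
        low, high = mean * (1 - half), mean * (1 + half)
        shape, scale = gamma_from_mean_range(mean, low, high)
        se = (high - low) / 3.92
        assert shape * scale**2 == pytest.approx(se * se, rel=1e-9)

    def test_empirical_mean_within_monte_carlo_error(self):
        shape, scale = gamma_from_mean_range(100.0, 80.0, 120.0)
        sd = (120.0 - 80.0) / 3.92
        assert sd == pytest.approx(10.204, abs=1e-3)
        draws = stats.gamma(shape, scale=scale).rvs(10**6, random_state=0)
        assert abs(draws.mean() - 100.0) < 3 * sd / 1000.0

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValidationError):
            gamma_from_mean_range(-5.0, 1.0, 2.0)


def _zero_width(config):
    params = {
        name: dataclasses.replace(spec, low=spec.base, high=spec.base)
        for name, spec in config.parameters.items()
    }
    return dataclasses.replace(config, parameters=params)


class TestOneWayDsa:
    def test_zero_width_ranges_reproduce_base_icer(self, fixture_config):
        cfg = _zero_width(fixture_config)
        base, _ = evaluate_config(cfg)
        for entry in one_way_dsa(cfg):
            assert entry.icer_low == pytest.approx(base.icer, rel=1e-12)
            assert entry.icer_high == pytest.approx(base.icer, rel=1e-12)
            assert entry.spread == 0.0

    def test_unread_parameter_has_zero_spread(self, fixture_config):
        # w_br is not read in the default (direct) utility mode
        [entry] = one_way_dsa(fixture_config, parameters=["w_br"])
        assert entry.spread == pytest.approx(0.0, abs=1e-9)

    def test_entries_sorted_by_spread(self, fixture_config):
        entries = one_way_dsa(fixture_config)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)
        assert len(entries) == len(fixture_config.parameters)

    def test_toy_cost_parameter_endpoints_hand_computed(self, fixture_config):
        """Varying a pure CRT-side cost +/-20% shifts the ICER by
        delta_cost/delta_effect computable by hand."""
        base, _ = evaluate_config(fixture_config)
        [entry] = one_way_dsa(fixture_config, parameters=["c_imrt_fraction"])
        spec = fixture_config.parameters["c_imrt_fraction"]
        d_eff = base.incremental_effectiveness
        # CRT charges 39 undiscounted fractions at entry; UHRT none
        expected_low = base.icer + 39 * (spec.low - spec.base) / d_eff
        expected_high = base.icer + 39 * (spec.high - spec.base) / d_eff
        assert entry.icer_low == pytest.approx(expected_low, rel=1e-9)
        assert entry.icer_high == pytest.approx(expected_high, rel=1e-9)

    def test_discount_rate_direction_matches_reported_crossover(self, fixture_config):
        """ICER rises with the discount rate (the reported crossover direction:
        the reference arm stops being cost-effective as the rate grows)."""
        [entry] = one_way_dsa(fixture_config, parameters=["discount_rate"])
        assert entry.icer_high > entry.icer_low
        grid = np.linspace(0.0, 0.08, 9)
        icers = [
            evaluate_config(fixture_config, {"discount_rate": r})[0].icer
            for r in grid
        ]
        assert all(b > a for a, b in zip(icers, icers[1:]))

    def test_dataframe_export_columns(self, fixture_config):
        df = dsa_to_dataframe(one_way_dsa(fixture_config, parameters=["u_ps"]))
        assert list(df.columns) == [
            "parameter", "low", "high", "icer_low", "icer_high",
            "flag_low", "flag_high", "spread",
        ]


class TestRunPsa:
    def test_degenerate_distributions_reproduce_base_case(self, fixture_config):
        cfg = _zero_width(fixture_config)
        base, _ = evaluate_config(cfg)
        samples = run_psa(cfg, n_draws=20, seed=0)
        for s in samples:
            assert s.outcomes["crt"][0] == pytest.approx(base.cost_ref, rel=1e-12)
            assert s.outcomes["crt"][1] == pytest.approx(base.qaly_ref, rel=1e-12)
            assert s.outcomes["uhrt"][0] == pytest.approx(base.cost_comp, rel=1e-12)

    def test_same_seed_identical_draws(self, fixture_config):
        a = run_psa(fixture_config, n_draws=10, seed=7)
        b = run_psa(fixture_config, n_draws=10, seed=7)
        assert [s.values for s in a] == [s.values for s in b]
        assert [s.outcomes for s in a] == [s.outcomes for s in b]

    def test_sampled_values_respect_domains(self, fixture_config):
        for s in run_psa(fixture_config, n_draws=50, seed=1):
            for name, v in s.values.items():
                spec = fixture_config.parameters[name]
                if spec.dist_family == "beta":
                    assert 0.0 <= v <= 1.0
                elif spec.dist_family == "gamma":
                    assert v >= 0.0

    def test_invalid_draw_count_rejected(self, fixture_config):
        with pytest.raises(ValidationError):
            run_psa(fixture_config, n_draws=0, seed=0)


def _toy_samples():
    # two hand-written draws with known NMB orderings
    return [
        PSASample(0, {}, {"crt": (100.0, 2.0), "uhrt": (100.0, 1.0)}),
        PSASample(1, {}, {"crt": (200.0, 2.0), "uhrt": (100.0, 1.0)}),
    ]


class TestCeac:
    def test_enumerated_probabilities_on_toy_draws(self):
        # wtp=0: costs 100 vs 100 tie (0.5) and 200 vs 100 loss (0) -> 0.25
        # wtp=100: diffs 100*1-0=+100 and +100-100=0 -> (1 + 0.5)/2 = 0.75
        # wtp=1000: both positive -> 1.0
        points = ceac(_toy_samples(), [0.0, 100.0, 1000.0], reference="crt")
        assert [p.prob_cost_effective for p in points] == [0.25, 0.75, 1.0]

    def test_zero_wtp_counts_cheaper_arm(self, fixture_config):
        samples = run_psa(fixture_config, n_draws=100, seed=2)
        [p] = ceac(samples, [0.0])
        cheaper = np.mean(
            [s.outcomes["crt"][0] < s.outcomes["uhrt"][0] for s in samples]
        )
        assert p.prob_cost_effective == pytest.approx(cheaper)

    def test_infinite_wtp_limit_counts_more_effective_arm(self, fixture_config):
        samples = run_psa(fixture_config, n_draws=100, seed=2)
        [p] = ceac(samples, [1e12])
        more_eff = np.mean(
            [s.outcomes["crt"][1] > s.outcomes["uhrt"][1] for s in samples]
        )
        assert p.prob_cost_effective == pytest.approx(more_eff)

    def test_reference_and_comparator_probabilities_sum_to_one(self, fixture_config):
        samples = run_psa(fixture_config, n_draws=200, seed=3)
        grid = [0.0, 10000.0, 31510.0, 100000.0]
        p_ref = ceac(samples, grid, reference="crt")
        p_comp = ceac(samples, grid, reference="uhrt")
        for a, b in zip(p_ref, p_comp):
            assert a.prob_cost_effective + b.prob_cost_effective == pytest.approx(1.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            ceac(_toy_samples(), [])


class TestThresholdSearch:
    def test_wtp_crossover_is_exactly_the_icer(self, fixture_config):
        base, _ = evaluate_config(fixture_config)
        res = threshold_search(fixture_config, "wtp", (0.0, 200000.0))
        assert res.found
        assert res.value == pytest.approx(base.icer, abs=1e-6)

    def test_wtp_crossover_linearity_on_published_increments(self, fixture_config):
        """With increments held fixed, NMB is linear in WTP and crosses zero
        at exactly incremental cost / incremental effectiveness."""
        res = threshold_search(fixture_config, "wtp", (0.0, 200000.0))
        base, _ = evaluate_config(fixture_config)
        analytic = base.incremental_cost / base.incremental_effectiveness
        assert res.value == pytest.approx(analytic, abs=1e-6)

    def test_constant_decision_reports_no_crossover(self, fixture_config):
        res = threshold_search(fixture_config, "c_transport", (1.16, 1.74))
        assert not res.found and res.value is None

    def test_parameter_knob_with_analytic_crossover(self, fixture_config):
        """The CRT-specific IMRT fee enters incremental cost linearly
        (39 undiscounted fractions), so the crossover is available in closed
        form and bisection must match it."""
        base, _ = evaluate_config(fixture_config)
        wtp = fixture_config.settings.wtp_per_qaly
        nmb_diff = wtp * base.incremental_effectiveness - base.incremental_cost
        x_star = fixture_config.parameters["c_imrt_fraction"].base + nmb_diff / 39.0
        res = threshold_search(
            fixture_config, "c_imrt_fraction", (0.0, 2000.0)
        )
        assert res.found
        assert res.value == pytest.approx(x_star, abs=1e-5)

    def test_unknown_knob_rejected(self, fixture_config):
        with pytest.raises(ValidationError):
            threshold_search(fixture_config, "nope", (0.0, 1.0))
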