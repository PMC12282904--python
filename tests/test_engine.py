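"""Cohort engine: transition structure, propagation, accrual, microsim."""

import copy

import numpy as np
import pytest

import htnscreen as hs
from htnscreen.engine import (
    DEAD_CVD,
    DEAD_NONCVD,
    HEALTHY,
    HTN_OFF,
    HTN_ON,
    N_STATES,
    POST_MI,
    POST_SA,
    POST_STROKE,
    POST_TIA,
    POST_UA,
)
from htnscreen.synthetic import ScheduleSpec, generate_schedule


def _constant_schedules(params, levels):
    """Copy of params with every schedule constant at the given level."""
    out = copy.deepcopy(params)
    for name in out.schedules:
        out.schedules[name] = generate_schedule(
            ScheduleSpec(name, "constant", levels.get(name, 0.0), levels.get(name, 0.0))
        )
    return out


def _all_in(params, state_field):
    out = copy.deepcopy(params)
    out.initial.healthy = 1.0 if state_field == "healthy" else 0.0
    out.initial.htn_off_tx = 1.0 if state_field == "htn_off_tx" else 0.0
    out.initial.htn_on_tx = 1.0 if state_field == "htn_on_tx" else 0.0
    return out


@pytest.fixture()
def frozen_params(base_params):
    """All schedules zero: no events, no mortality, no background flows."""
    return _constant_schedules(base_params, {})


class TestTransitionRow:
    def test_dead_states_absorbing(self, base_params):
        for state in (DEAD_CVD, DEAD_NONCVD):
            row = hs.transition_row(state, 45, False, base_params)
            expected = np.zeros(N_STATES)
            expected[state] = 1.0
            assert np.allclose(row, expected)

    @pytest.mark.parametrize("age", [30, 45, 69, 99])
    @pytest.mark.parametrize("screen", [False, True])
    def test_rows_are_distributions(self, base_params, age, screen):
        for state in range(N_STATES):
            row = hs.transition_row(state, age, screen, base_params)
            assert np.all(row >= 0)
            assert row.sum() == pytest.approx(1.0, abs=1e-12)

    def test_treated_event_inflow_scaled_by_relative_risk(self, base_params):
        """On-treatment stroke inflow is the untreated probability times the
        published relative risk 0.622 (CHD likewise via 0.675)."""
        p = _constant_schedules(
            base_params, {"untreated_chd": 0.02, "untreated_stroke": 0.01}
        )
        row = hs.transition_row(HTN_ON, 40, False, p)
        sb = p.decomposition.stroke_branch()
        stroke_event_mass = 0.01 * p.effects.rr_stroke_on_treatment
        assert row[POST_STROKE] == pytest.approx(stroke_event_mass * sb["nonfatal"])
        assert row[POST_TIA] == pytest.approx(stroke_event_mass * sb["tia"])
        cb = p.decomposition.chd_branch()
        chd_event_mass = 0.02 * p.effects.rr_chd_on_treatment
        assert row[POST_MI] == pytest.approx(chd_event_mass * cb["mi"])

    def test_event_split_uses_renormalized_branch(self, base_params):
        """Fatal share of a CHD event is 0.122/1.043 after renormalizing the
        printed branch."""
        p = _constant_schedules(base_params, {"healthy_chd": 1.0})
        row = hs.transition_row(HEALTHY, 40, False, p)
        assert row[DEAD_CVD] == pytest.approx(0.122 / 1.043)
        assert row[POST_MI] == pytest.approx(0.261 / 1.043)
        assert row[POST_SA] == pytest.approx(0.503 / 1.043)
        assert row[POST_UA] == pytest.approx(0.157 / 1.043)

    def test_noncvd_death_competes_first(self, base_params):
        p = _constant_schedules(
            base_params, {"noncvd_death": 0.1, "healthy_chd": 0.5}
        )
        row = hs.transition_row(HEALTHY, 40, False, p)
        assert row[DEAD_NONCVD] == pytest.approx(0.1)
        # events act on the surviving 0.9
        assert row[POST_MI] == pytest.approx(0.9 * 0.5 * 0.261 / 1.043)


class TestRunCohort:
    def test_identity_dynamics_keep_occupancy_constant(self, frozen_params):
        trace = hs.run_cohort(hs.strategy_by_label("No screening"), frozen_params)
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_initial_occupancy_is_renormalized_entry_split(self, base_params, roster):
        trace = hs.run_cohort(roster[1], base_params)
        h, off, on = base_params.initial.as_tuple()
        assert trace.occupancy[0, HEALTHY] == pytest.approx(h)
        assert trace.occupancy[0, HTN_OFF] == pytest.approx(off)
        assert trace.occupancy[0, HTN_ON] == pytest.approx(on)

    def test_mass_conserved_all_strategies_all_cycles(self, base_params, roster):
        for strat in roster:
            trace = hs.run_cohort(strat, base_params)
            assert trace.occupancy.shape[0] == base_params.config.n_cycles
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(trace.occupancy >= -1e-15)

    def test_blind_screening_is_noop_on_occupancy(self, base_params):
        """A test with zero sensitivity and perfect specificity flags nobody,
        so state trajectories match no screening exactly (only contact costs
        differ). Untreated risks are held at the screen-cycle levels so
        false-negative status carries identical event risk."""
        p = _constant_schedules(
            copy.deepcopy(base_params),
            {
                "untreated_chd": base_params.post_risks.event_risk_false_negative_chd,
                "untreated_stroke": base_params.post_risks.event_risk_false_negative_stroke,
                "healthy_chd": 0.01,
                "noncvd_death": 0.005,
                "htn_incidence": 0.02,
                "treatment_uptake": 0.1,
            },
        )
        p = p.with_value("screening.sensitivity", 0.0)
        p = p.with_value("screening.specificity", 1.0)
        p.screening.p_false_positive = None  # consistency field not under test
        screened = hs.run_cohort(
            hs.strategy_by_label("Annual screening from the age of 30"), p
        )
        unscreened = hs.run_cohort(hs.strategy_by_label("No screening"), p)
        assert np.allclose(screened.occupancy, unscreened.occupancy, atol=1e-14)
        assert screened.cycle_costs.sum() > unscreened.cycle_costs.sum()

    def test_screening_component_cost_monotone_in_frequency(self, base_params):
        """Annual >= biennial >= triennial screening+confirmatory outlay for
        a fixed start age."""
        def screen_cost(label):
            t = hs.run_cohort(hs.strategy_by_label(label), base_params)
            return (t.cost_components["screening"] + t.cost_components["confirmatory"]).sum()

        for start in (30, 40, 50):
            annual = screen_cost(f"Annual screening from the age of {start}")
            biennial = screen_cost(f"Screening every two years from the age of {start}")
            triennial = screen_cost(f"Screening every three years from the age of {start}")
            assert annual >= biennial >= triennial

    def test_false_negatives_carry_untreated_risk_between_rounds(self, base_params):
        """Between screening rounds, previously screened-negative untreated
        mass faces the ordinary untreated schedule: a sparse strategy's
        untreated row equals no-screening's in off-round cycles."""
        s = hs.strategy_by_label("Screening every three years from the age of 30")
        age = 31  # off-round
        row_s = hs.transition_row(HTN_OFF, age, hs.is_screening_cycle(s, age), base_params)
        row_n = hs.transition_row(HTN_OFF, age, False, base_params)
        assert np.allclose(row_s, row_n)


class TestAccrue:
    def test_fixed_healthy_cohort_matches_discount_annuity(self, frozen_params):
        p = _all_in(frozen_params, "healthy")
        res = hs.evaluate_strategy(hs.strategy_by_label("No screening"), p)
        r, n = 0.05, p.config.n_cycles
        annuity = sum((1 + r) ** -t for t in range(n))
        assert res.total_qaly == pytest.approx(annuity, abs=1e-9)

    def test_zero_discount_constant_cost_stream(self, frozen_params):
        p = _all_in(frozen_params, "htn_on_tx")
        p.config.discount_rate_costs = 0.0
        res = hs.evaluate_strategy(hs.strategy_by_label("No screening"), p)
        assert res.total_cost == pytest.approx(70 * p.costs.tx_previous)

    def test_all_zero_utilities_give_zero_qalys(self, frozen_params):
        p = copy.deepcopy(frozen_params)
        for f in ("healthy", "htn_off_tx", "htn_on_tx", "post_mi", "post_stroke",
                  "post_sa", "post_tia", "post_ua"):
            setattr(p.utilities, f, 0.0)
        res = hs.evaluate_strategy(hs.strategy_by_label("No screening"), p)
        assert res.total_qaly == 0.0

    def test_discounted_never_exceeds_undiscounted(self, base_params, roster):
        trace = hs.run_cohort(roster[1], base_params)
        assert np.all(trace.cycle_costs_disc <= trace.cycle_costs + 1e-12)
        assert np.all(trace.cycle_qalys_disc <= trace.cycle_qalys + 1e-12)


class TestMicrosimOracle:
    def test_deterministic_dynamics_exact(self, frozen_params):
        p = _all_in(frozen_params, "healthy")
        s = hs.strategy_by_label("No screening")
        micro = hs.microsim_oracle(s, p, 500, seed=1)
        cohort = hs.evaluate_strategy(s, p)
        assert micro.total_qaly == pytest.approx(cohort.total_qaly, abs=1e-9)
        assert micro.total_cost == pytest.approx(cohort.total_cost, abs=1e-9)

    def test_same_seed_identical(self, reduced_params):
        s = hs.strategy_by_label("Screening every two years from the age of 30")
        a = hs.microsim_oracle(s, reduced_params, 2000, seed=11)
        b = hs.microsim_oracle(s, reduced_params, 2000, seed=11)
        assert (a.total_cost, a.total_qaly) == (b.total_cost, b.total_qaly)

    @pytest.mark.parametrize(
        "label", ["No screening", "Annual screening from the age of 30"]
    )
    def test_cohort_within_three_se_of_microsim(self, reduced_params, label):
        s = hs.strategy_by_label(label)
        micro = hs.microsim_oracle(s, reduced_params, 100_000, seed=23)
        cohort = hs.evaluate_strategy(s, reduced_params)
        assert abs(cohort.total_cost - micro.total_cost) <= 3 * micro.se_cost
        assert abs(cohort.total_qaly - micro.total_qaly) <= 3 * micro.se_qaly
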