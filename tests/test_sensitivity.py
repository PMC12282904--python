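"""One-way and probabilistic sensitivity analysis."""

import copy
import dataclasses

import numpy as np
import pytest

import htnscreen as hs
from htnscreen.sensitivity import DSASpec, _fit, run_owsa


def _all_fixed(params):
    """Copy of the parameter set with every CI stripped (degenerate PSA)."""
    out = copy.deepcopy(params)
    out.uncertainty = {
        k: dataclasses.replace(v, ci_low=None, ci_high=None)
        for k, v in out.uncertainty.items()
    }
    return out


@pytest.fixture(scope="module")
def two_strategies():
    return [
        hs.strategy_by_label("No screening"),
        hs.strategy_by_label("Screening every two years from the age of 30"),
    ]


class TestDistributionAssignment:
    def test_beta_fit_recovers_mean_within_two_percent(self, base_params):
        pv = base_params.uncertainty["screening.specificity"]
        d = _fit(pv)
        assert d.family == "beta"
        assert d.mean() == pytest.approx(0.746, rel=0.02)

    def test_gamma_fit_recovers_mean_within_two_percent(self, base_params):
        pv = base_params.uncertainty["costs.tx_previous"]
        d = _fit(pv)
        assert d.family == "gamma"
        assert d.mean() == pytest.approx(57.56, rel=0.02)

    def test_no_ci_is_fixed(self, base_params):
        d = _fit(base_params.uncertainty["costs.confirmatory_workup"])
        assert d.family == "fixed"
        assert d.mean() == 212.57

    def test_relative_risks_get_positive_support_family(self, base_params):
        d = _fit(base_params.uncertainty["effects.rr_chd_recurrence"])
        assert d.family == "gamma"
        assert d.mean() == pytest.approx(2.4, rel=0.02)

    def test_infeasible_beta_falls_back_to_fixed(self):
        pv = hs.ParameterValue(
            name="x", value=0.5, kind="probability", ci_low=0.0, ci_high=3.0
        )
        assert _fit(pv).family == "fixed"

    def test_every_parameter_gets_an_assignment(self, base_params):
        assignments = hs.assign_distributions(base_params)
        assert len(assignments) == len(base_params.uncertainty)
        families = {a.family for a in assignments}
        assert families == {"beta", "gamma", "fixed"}


class TestOWSA:
    def test_zero_width_spec_gives_zero_bar(self, reduced_params, two_strategies):
        spec = DSASpec("utilities.post_stroke", 0.629, 0.629, 0.629)
        df = run_owsa(reduced_params, [spec], two_strategies)
        assert np.allclose(df["width"], 0.0)

    def test_outcome_discounting_monotone(self, reduced_params, two_strategies):
        spec = DSASpec("config.discount_rate_outcomes", 0.03, 0.05, 0.07)
        df = run_owsa(
            reduced_params, [spec], two_strategies, outcome="qaly"
        )
        assert (df["outcome_low"] > df["outcome_high"]).all()
        assert (df["outcome_low"] > df["outcome_base"]).all()

    def test_rows_sorted_by_bar_width(self, reduced_params, two_strategies):
        specs = hs.default_owsa_specs(reduced_params)[:4]
        df = run_owsa(reduced_params, specs, two_strategies)
        for _, grp in df.groupby("strategy"):
            widths = grp["width"].to_numpy()
            assert np.all(np.diff(widths) <= 1e-12)

    def test_unknown_parameter_rejected(self, reduced_params, two_strategies):
        with pytest.raises(KeyError):
            run_owsa(
                reduced_params,
                [DSASpec("utilities.nonexistent", 0, 0.5, 1)],
                two_strategies,
            )

    def test_reversed_range_is_oriented(self):
        spec = DSASpec("p", 0.9, 0.5, 0.1)
        assert (spec.low, spec.high) == (0.1, 0.9)

    def test_default_specs_cover_discount_rates_and_cis(self, base_params):
        specs = hs.default_owsa_specs(base_params)
        names = {s.parameter for s in specs}
        assert "config.discount_rate_costs" in names
        assert "utilities.post_stroke" in names
        assert len(specs) == 14


class TestPSA:
    def test_degenerate_psa_reproduces_base_case_exactly(
        self, reduced_params, two_strategies
    ):
        fixed = _all_fixed(reduced_params)
        psa = hs.run_psa(fixed, two_strategies, 5, seed=3)
        for j, s in enumerate(two_strategies):
            base = hs.evaluate_strategy(s, fixed)
            assert np.allclose(psa.costs[:, j], base.total_cost)
            assert np.allclose(psa.qalys[:, j], base.total_qaly)

    def test_reproducible_given_seed(self, reduced_params, two_strategies):
        a = hs.run_psa(reduced_params, two_strategies, 5, seed=9)
        b = hs.run_psa(reduced_params, two_strategies, 5, seed=9)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.qalys, b.qalys)
        assert np.array_equal(a.draws, b.draws)

    def test_matrices_complete(self, reduced_params, two_strategies):
        psa = hs.run_psa(reduced_params, two_strategies, 4, seed=1)
        assert psa.costs.shape == (4, 2)
        assert np.isfinite(psa.costs).all() and np.isfinite(psa.qalys).all()
        assert psa.draws.shape[0] == 4

    def test_centered_distributions_converge_to_base_case(
        self, base_params, two_strategies
    ):
        """Strategy-level PSA means stay within Monte-Carlo error of the
        deterministic run on a shortened horizon."""
        p = base_params.with_value("config.n_cycles", 20)
        n = 300
        psa = hs.run_psa(p, two_strategies, n, seed=17)
        for j, s in enumerate(two_strategies):
            base = hs.evaluate_strategy(s, p)
            se_c = psa.costs[:, j].std(ddof=1) / np.sqrt(n)
            se_q = psa.qalys[:, j].std(ddof=1) / np.sqrt(n)
            assert abs(psa.costs[:, j].mean() - base.total_cost) <= 3 * se_c
            assert abs(psa.qalys[:, j].mean() - base.total_qaly) <= 3 * se_q


@pytest.fixture(scope="module")
def small_psa(base_params):
    strategies = [
        hs.strategy_by_label("No screening"),
        hs.strategy_by_label("Screening every three years from the age of 30"),
        hs.strategy_by_label("Annual screening from the age of 30"),
    ]
    p = base_params.with_value("config.n_cycles", 20)
    return strategies, hs.run_psa(p, strategies, 100, seed=5)


class TestCEACAndScatter:
    def test_probabilities_partition_at_every_wtp(self, small_psa):
        _, psa = small_psa
        grid = np.linspace(0, 60000, 13)
        curves = hs.ceac(psa, grid)
        totals = curves.drop(columns="wtp").sum(axis=1)
        assert np.allclose(totals, 1.0, atol=1e-12)

    def test_wtp_zero_rewards_cost_minimizers_only(self, small_psa):
        _, psa = small_psa
        curves = hs.ceac(psa, [0.0]).drop(columns="wtp")
        winners_by_cost = psa.costs.argmin(axis=1)
        for j, s in enumerate(psa.strategies):
            assert curves[s].iloc[0] == pytest.approx(np.mean(winners_by_cost == j))

    def test_degenerate_psa_gives_zero_one_step_curve(self, reduced_params, small_psa):
        strategies, _ = small_psa
        fixed = _all_fixed(reduced_params)
        psa = hs.run_psa(fixed, strategies, 3, seed=1)
        curves = hs.ceac(psa, np.linspace(0, 60000, 7)).drop(columns="wtp")
        assert set(np.unique(curves.to_numpy())) <= {0.0, 1.0}

    def test_acceptability_is_single_wtp_slice(self, small_psa):
        _, psa = small_psa
        at = hs.acceptability_at_wtp(psa, 20652.44)
        row = hs.ceac(psa, [20652.44]).iloc[0]
        for s in psa.strategies:
            assert at[s] == row[s]
        assert all(0.0 <= v <= 1.0 for v in at.values())

    def test_degenerate_acceptability_unit_mass_on_nmb_argmax(
        self, reduced_params, small_psa
    ):
        strategies, _ = small_psa
        fixed = _all_fixed(reduced_params)
        psa = hs.run_psa(fixed, strategies, 2, seed=1)
        at = hs.acceptability_at_wtp(psa, 20652.44)
        results = [hs.evaluate_strategy(s, fixed) for s in strategies]
        base = results[0]
        best = max(
            results, key=lambda r: (hs.nmb(r, base, 20652.44), -r.total_cost)
        ).strategy
        assert at[best] == 1.0

    def test_scatter_shapes_and_baseline_origin(self, small_psa):
        _, psa = small_psa
        pts = hs.scatter_data(psa, "No screening")
        for s in psa.strategies:
            assert len(pts[s]) == psa.iterations
        assert np.allclose(pts["No screening"].to_numpy(), 0.0)

    def test_scatter_unknown_baseline_rejected(self, small_psa):
        _, psa = small_psa
        with pytest.raises(ValueError):
            hs.scatter_data(psa, "nope")
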