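"""Probabilistic, one-way, threshold and scenario sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from stepcea import (
    DistributionSpec,
    apply_cost_differentiation,
    evaluate,
    one_way_dsa,
    run_psa,
    threshold_search,
)
from stepcea.uncertainty import dsa_bounds


def _degenerate_all(params):
    ps = params.copy_deep()
    ps.distributions = {
        name: DistributionSpec(
            family="degenerate",
            parameters={"value": ps.base_value(name)},
            range_rule=spec.range_rule,
            psa_exclude=spec.psa_exclude,
        )
        for name, spec in ps.distributions.items()
    }
    return ps


class TestPSA:
    def test_degenerate_distributions_reproduce_deterministic_run(self, toy_params):
        ps = _degenerate_all(toy_params)
        psa = run_psa(ps, 3, seed=11)
        ev = evaluate(ps)
        for _, row in psa.samples.iterrows():
            assert row["qalys_gained"] == ev.incremental.qalys_gained
            assert row["healthcare_cost_reduction"] == ev.incremental.healthcare_cost_reduction
        assert psa.summary.loc["qalys_gained", "p97.5"] == psa.summary.loc["qalys_gained", "p2.5"]

    def test_same_seed_is_bit_identical(self, toy_params):
        a = run_psa(toy_params, 25, seed=5)
        b = run_psa(toy_params, 25, seed=5)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_different_seeds_differ(self, toy_params):
        a = run_psa(toy_params, 10, seed=1)
        b = run_psa(toy_params, 10, seed=2)
        assert not a.samples["qalys_gained"].equals(b.samples["qalys_gained"])

    def test_percentiles_match_sorting_oracle(self, toy_params):
        psa = run_psa(toy_params, 40, seed=3)
        x = np.sort(psa.samples["qalys_gained"].to_numpy())
        # linear interpolation between order statistics at quantile q:
        # h = q*(n-1); value = x[floor(h)] + frac*(x[floor(h)+1]-x[floor(h)])
        for q, col in ((0.025, "p2.5"), (0.975, "p97.5")):
            h = q * (len(x) - 1)
            lo = int(np.floor(h))
            expected = x[lo] + (h - lo) * (x[min(lo + 1, len(x) - 1)] - x[lo])
            assert psa.summary.loc["qalys_gained", col] == pytest.approx(expected, rel=1e-12)

    def test_time_horizon_never_sampled(self, toy_params):
        names = toy_params.uncertain_parameters(include_psa_excluded=False)
        assert "horizon_years" not in names
        assert "horizon_years" in toy_params.uncertain_parameters(include_psa_excluded=True)

    def test_psa_mean_converges_with_more_samples(self, toy_params):
        # law of large numbers: SE of the mean shrinks roughly as 1/sqrt(n)
        small = [
            run_psa(toy_params, 16, seed=s).samples["qalys_gained"].mean() for s in range(8)
        ]
        large = [
            run_psa(toy_params, 64, seed=100 + s).samples["qalys_gained"].mean() for s in range(8)
        ]
        assert np.std(large) < np.std(small)


class TestOneWayDSA:
    def test_range_rules(self, toy_params):
        lo, hi, _ = dsa_bounds(toy_params, "program_cost_annual")
        base = toy_params.program_cost_annual
        assert lo == pytest.approx(0.7 * base) and hi == pytest.approx(1.3 * base)
        spec = toy_params.distributions["cost_inpatient.diabetes"]
        lo, hi, _ = dsa_bounds(toy_params, "cost_inpatient.diabetes")
        assert lo == pytest.approx(spec.ppf(0.25)) and hi == pytest.approx(spec.ppf(0.75))

    def test_out_of_domain_bound_clamped_with_flag(self, toy_copy):
        toy_copy.inpatient_proportion["diabetes"] = 0.9
        toy_copy.distributions["inpatient_proportion.diabetes"] = DistributionSpec(
            family="beta", parameters={"alpha": 9, "beta": 1}, range_rule="pm30"
        )
        lo, hi, clamped = dsa_bounds(toy_copy, "inpatient_proportion.diabetes")
        assert clamped and hi == 1.0  # 0.9 * 1.3 exceeds the probability domain

    def test_zero_width_bounds_give_zero_width_bar(self, toy_copy):
        toy_copy.distributions = {
            "program_cost_annual": DistributionSpec(
                family="degenerate",
                parameters={"value": toy_copy.program_cost_annual},
                range_rule="ci95",
            )
        }
        table = one_way_dsa(toy_copy, names=["program_cost_annual"])
        assert table.loc[0, "bar_width"] == 0.0

    def test_ignored_parameter_leaves_icer_unchanged(self, toy_copy):
        # utility of an unpopulated state with zero inflow cannot move the ICER
        for lbl in toy_copy.band_labels:
            toy_copy.complication_incidence[lbl]["diabetes"] = 0.0
        table = one_way_dsa(toy_copy, names=["utilities.diabetes_cvd"])
        base_icer = evaluate(toy_copy).incremental.icer()
        assert table.loc[0, "icer_low"] == pytest.approx(base_icer, rel=1e-9)
        assert table.loc[0, "icer_high"] == pytest.approx(base_icer, rel=1e-9)

    def test_affine_parameter_bar_equals_slope_times_range(self, toy_params):
        # the ICER is exactly affine in the annual program cost
        lo, hi, _ = dsa_bounds(toy_params, "program_cost_annual")
        table = one_way_dsa(toy_params, names=["program_cost_annual"])
        e1 = evaluate(toy_params).incremental
        annuity = sum((1 + toy_params.discount_rate) ** -t for t in range(1, toy_params.horizon_years + 1))
        slope = annuity / e1.qalys_gained
        assert table.loc[0, "bar_width"] == pytest.approx(slope * (hi - lo), rel=1e-9)

    def test_entries_sorted_by_bar_width_and_order_invariant(self, toy_params):
        names = ["program_cost_annual", "compliance", "cost_inpatient.diabetes_cvd"]
        t1 = one_way_dsa(toy_params, names=names)
        t2 = one_way_dsa(toy_params, names=list(reversed(names)))
        assert (t1["bar_width"].to_numpy() == np.sort(t1["bar_width"])[::-1]).all()
        pd.testing.assert_frame_equal(t1, t2)


class TestThreshold:
    def test_affine_root_found_analytically(self, toy_params):
        # ICER = (annuity*x - red)/dq crosses zero at x = red/annuity
        ev = evaluate(toy_params).incremental
        annuity = sum((1 + toy_params.discount_rate) ** -t for t in range(1, toy_params.horizon_years + 1))
        analytic = ev.healthcare_cost_reduction / annuity
        res = threshold_search(toy_params, "program_cost_annual", (0.0, 80e6))
        assert res is not None
        assert res.threshold == pytest.approx(analytic, rel=1e-4)
        assert abs(res.icer_at_threshold) <= 1.0  # SGD/QALY, essentially zero

    def test_bisection_matches_grid_scan_oracle(self, toy_params):
        res = threshold_search(toy_params, "program_cost_annual", (0.0, 80e6))
        grid = np.linspace(0.0, 80e6, 401)
        signs = []
        for x in grid:
            ps = toy_params.copy_deep()
            ps.set_value("program_cost_annual", float(x))
            signs.append(np.sign(evaluate(ps).incremental.icer()))
        signs = np.asarray(signs)
        flips = np.nonzero(np.diff(signs))[0]
        assert len(flips) == 1
        lo, hi = grid[flips[0]], grid[flips[0] + 1]
        assert lo <= res.threshold <= hi

    def test_no_sign_change_returns_none(self, toy_params):
        res = threshold_search(toy_params, "program_cost_annual", (50e6, 80e6))
        assert res is None

    def test_compliance_threshold_exists_at_full_scale(self, full_params):
        res = threshold_search(full_params, "compliance", (0.0, 1.0), tol=1e-4)
        assert res is not None and res.direction == "at_least"
        assert 0.0 < res.threshold < full_params.compliance


class TestScenario:
    def test_delta_zero_is_identity(self, toy_params):
        ps = apply_cost_differentiation(toy_params, 0.0)
        assert ps.pa_cost_multiplier == toy_params.pa_cost_multiplier

    def test_multipliers(self, toy_params):
        ps = apply_cost_differentiation(toy_params, 0.05)
        assert ps.pa_cost_multiplier["inactive"] == pytest.approx(1.05)
        assert ps.pa_cost_multiplier["low"] == pytest.approx(1.0)
        assert ps.pa_cost_multiplier["mod_high"] == pytest.approx(0.95)
        from stepcea.cohort import cost_vectors
        from stepcea.states import state_index

        base_dir, _ = cost_vectors(toy_params)
        new_dir, _ = cost_vectors(ps)
        i = state_index("diabetes", "inactive")
        assert new_dir[i] == pytest.approx(1.05 * base_dir[i])
        j = state_index("diabetes_cvd")
        assert new_dir[j] == base_dir[j]  # complications untouched

    def test_scenario_increases_cost_reduction(self, full_params):
        base = evaluate(full_params).incremental.healthcare_cost_reduction
        scen = evaluate(apply_cost_differentiation(full_params, 0.05)).incremental.healthcare_cost_reduction
        assert scen > base
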