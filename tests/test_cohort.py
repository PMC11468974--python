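"""Cohort initialization, Markov trace, and discounted outcome accumulation."""

import numpy as np
import pytest

from stepcea import (
    accumulate_outcomes,
    estimate_cohort_size,
    generate_parameter_set,
    half_cycle_effective,
    initialize_cohort,
    project_prevalence,
    run_markov_trace,
    run_situation,
)
from stepcea.states import DEAD, LIVING, state_index

LEVELS = ("inactive", "low", "mod_high")


class TestCohortSize:
    def test_registrants_times_completion(self):
        assert estimate_cohort_size(1_700_000, 0.385) == pytest.approx(654_500)

    def test_completion_one_is_identity(self):
        assert estimate_cohort_size(123.0, 1.0) == 123.0

    def test_observed_completion_fraction(self):
        # 266,000 of 690,233 tracker-syncing participants
        assert round(100 * 266_000 / 690_233, 1) == 38.5

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            estimate_cohort_size(100, 1.5)


class TestInitialization:
    def test_point_mass_config(self, toy_copy):
        for lbl in toy_copy.band_labels:
            toy_copy.disease_prevalence[lbl] = {
                "healthy": 1.0, "diabetes": 0.0, "hypertension": 0.0,
            }
        toy_copy.pa_prevalence["healthy"] = {"inactive": 1.0, "low": 0.0, "mod_high": 0.0}
        occ = initialize_cohort(toy_copy, 500.0)
        assert occ.sum() == pytest.approx(500.0)
        assert occ[:, state_index("healthy", "inactive")].sum() == pytest.approx(500.0)

    def test_product_allocation(self, toy_copy):
        lbl = toy_copy.band_labels[0]
        occ = initialize_cohort(toy_copy, 1000.0)
        band = toy_copy.age_bands[0]
        expected = (
            1000.0
            * band.fraction
            * toy_copy.disease_prevalence[lbl]["diabetes"]
            * toy_copy.pa_prevalence["diabetes"]["low"]
        )
        assert occ[0, state_index("diabetes", "low")] == pytest.approx(expected)

    def test_conservation_over_random_draws(self):
        for seed in range(100):
            ps = generate_parameter_set(seed, "toy")
            occ = initialize_cohort(ps, 654_500.0)
            assert occ.sum() == pytest.approx(654_500.0, abs=1e-6)


class TestTrace:
    def test_static_model_constant_occupancy(self, quiet_params):
        occ0 = initialize_cohort(quiet_params, 1000.0)
        trace = run_markov_trace(occ0, quiet_params, "intervention")
        for t in range(trace.n_cycles + 1):
            assert np.allclose(trace.by_state[t], trace.by_state[0])
        assert trace.incident.to_numpy().sum() == 0.0

    def test_constant_death_probability_hand_example(self, quiet_params):
        # 10% annual death probability: survivors 100 -> 90 -> 81
        ps = quiet_params.copy_deep()
        rate = -np.log(0.9)  # probability 0.1 per cycle
        for lbl in ps.band_labels:
            ps.mortality[lbl] = rate
        for g in ("healthy", "diabetes", "hypertension"):
            ps.rr_mortality[g] = {"inactive": 1.0, "low": 1.0, "mod_high": 1.0}
        occ0 = initialize_cohort(ps, 100.0)
        trace = run_markov_trace(occ0, ps, "control")
        alive = trace.by_state[:, list(LIVING)].sum(axis=1)
        assert alive[1] == pytest.approx(90.0, abs=1e-9)
        assert alive[2] == pytest.approx(81.0, abs=1e-9)
        assert trace.incident.loc[2, "deaths"] == pytest.approx(9.0, abs=1e-9)

    def test_conservation_and_monotone_deaths(self, full_params):
        n = 654_500.0
        for situation in ("intervention", "control"):
            trace, _ = run_situation(full_params, situation, n)
            totals = trace.by_state.sum(axis=1)
            assert np.abs(totals - n).max() <= 1e-6
            dead = trace.by_state[:, DEAD]
            assert (np.diff(dead) >= -1e-9).all()

    def test_dimension_mismatch_rejected(self, toy_params):
        with pytest.raises(ValueError):
            run_markov_trace(np.zeros((2, 12)), toy_params, "control")


class TestHalfCycle:
    def test_constant_unchanged(self):
        occ = np.full(12, 7.0)
        assert np.array_equal(half_cycle_effective(occ, occ), occ)

    def test_trapezoid(self):
        assert half_cycle_effective(np.array([100.0]), np.array([80.0]))[0] == 90.0

    def test_zero(self):
        assert half_cycle_effective(np.zeros(3), np.zeros(3)).sum() == 0.0


class TestOutcomes:
    def _immortal_unit_cohort(self, quiet_params, r):
        ps = quiet_params.copy_deep()
        ps.utilities["healthy"] = {"inactive": 1.0, "low": 1.0, "mod_high": 1.0}
        for lbl in ps.band_labels:
            ps.disease_prevalence[lbl] = {"healthy": 1.0, "diabetes": 0.0, "hypertension": 0.0}
        ps.discount_rate = r
        occ0 = initialize_cohort(ps, 1.0)
        trace = run_markov_trace(occ0, ps, "control")
        return accumulate_outcomes(trace, ps)

    def test_undiscounted_annuity(self, quiet_params):
        out = self._immortal_unit_cohort(quiet_params, 0.0)
        assert out.qalys == pytest.approx(10.0, abs=1e-9)

    def test_discounted_annuity(self, quiet_params):
        # sum over 10 years of 1.03^-t
        expected = sum(1.03 ** -t for t in range(1, 11))
        out = self._immortal_unit_cohort(quiet_params, 0.03)
        assert expected == pytest.approx(8.5302, abs=1e-4)
        assert out.qalys == pytest.approx(expected, rel=1e-12)

    def test_program_cost_stream(self, toy_params):
        _, summary = run_situation(toy_params, "intervention", 1000.0)
        annuity = sum(1.03 ** -t for t in range(1, 11))
        assert summary.program_cost == pytest.approx(36e6 * annuity, rel=1e-12)
        assert summary.program_cost / 1e6 == pytest.approx(307.09, abs=0.01)

    def test_control_has_no_program_cost(self, toy_params):
        _, summary = run_situation(toy_params, "control", 1000.0)
        assert summary.program_cost == 0.0

    def test_mid_cycle_convention(self, quiet_params):
        ps = quiet_params.copy_deep()
        ps.utilities["healthy"] = {"inactive": 1.0, "low": 1.0, "mod_high": 1.0}
        for lbl in ps.band_labels:
            ps.disease_prevalence[lbl] = {"healthy": 1.0, "diabetes": 0.0, "hypertension": 0.0}
        ps.discounting = "mid_cycle"
        occ0 = initialize_cohort(ps, 1.0)
        out = accumulate_outcomes(run_markov_trace(occ0, ps, "control"), ps)
        expected = sum(1.03 ** -(t - 0.5) for t in range(1, 11))
        assert out.qalys == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(8.657, abs=1e-3)

    def test_zero_discount_equals_plain_sums(self, toy_params):
        ps = toy_params.copy_deep()
        ps.discount_rate = 0.0
        trace, summary = run_situation(ps, "control", 1000.0)
        from stepcea.cohort import cost_vectors, utility_vector

        py = 0.5 * (trace.by_state[:-1] + trace.by_state[1:])
        assert summary.qalys == pytest.approx(float((py @ utility_vector(ps)).sum()), rel=1e-12)
        c_dir, _ = cost_vectors(ps)
        assert summary.direct_cost == pytest.approx(float((py @ c_dir).sum()), rel=1e-12)


class TestProjectedPrevalence:
    def test_year_zero_matches_initial_tables(self, toy_params):
        trace, _ = run_situation(toy_params, "control", 1000.0)
        prev = project_prevalence(trace, 0)
        expected_diab = sum(
            b.fraction * toy_params.disease_prevalence[b.label]["diabetes"]
            for b in toy_params.age_bands
        )
        assert prev["disease"]["diabetes"] == pytest.approx(expected_diab, rel=1e-9)
        assert sum(prev["disease"].values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(prev["pa"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_fractions_sum_to_one_over_horizon(self, full_params):
        trace, _ = run_situation(full_params, "intervention", 1000.0)
        for year in (0, 5, 10):
            prev = project_prevalence(trace, year)
            assert sum(prev["disease"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_two_cycle_shares(self, quiet_params):
        ps = quiet_params.copy_deep()
        rate = -np.log(0.8)
        for lbl in ps.band_labels:
            ps.mortality[lbl] = rate
        for g in ("healthy", "diabetes", "hypertension"):
            ps.rr_mortality[g] = {"inactive": 1.0, "low": 1.0, "mod_high": 1.0}
        trace, _ = run_situation(ps, "control", 100.0)
        prev = project_prevalence(trace, 2)
        # uniform death leaves living shares equal to the initial shares
        prev0 = project_prevalence(trace, 0)
        for g in prev["disease"]:
            assert prev["disease"][g] == pytest.approx(prev0["disease"][g], abs=1e-9)
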