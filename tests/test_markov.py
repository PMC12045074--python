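"""Markov cohort engine: probability transforms, transitions, accrual."""

import math

import numpy as np
import pandas as pd
import pytest

import tavicea as tc
from tavicea.acute import run_decision_tree
from tavicea.markov import (
    AW,
    DD,
    annual_prob_to_cycle_prob,
    apply_hazard_ratio,
    background_mortality,
    build_transition_matrix,
    discount_factors,
    life_years,
    median_survival,
    run_cohort,
    transition_stack,
)
from tavicea.params import LifeTable


def flat_life_table(annual_p: float, min_age=60, terminal=110) -> LifeTable:
    rows = []
    for sex in ("male", "female"):
        for age in range(min_age, terminal + 1):
            rows.append((age, sex, 1.0 if age == terminal else annual_p))
    return LifeTable.from_frame(
        pd.DataFrame(rows, columns=["age", "sex", "annual_mortality_prob"])
    )


def simple_ps(
    base_ps,
    annual_mortality=0.0,
    horizon_years=10.0,
    norm=0.8,
    discount=0.0,
    zero_morbidity=True,
    zero_costs=True,
):
    """A stripped-down parameter set for closed-form checks."""
    ps = base_ps.copy_deep()
    ps.life_table = flat_life_table(annual_mortality)
    ps.settings.horizon_years = horizon_years
    ps.settings.annual_discount_rate_costs = discount
    ps.settings.annual_discount_rate_outcomes = discount
    ps.utilities.population_norm_by_age_sex = [
        tc.AgeBandNorm(age_min=0, male=norm, female=norm)
    ]
    ps.utilities.decrement_af = 0.0
    ps.utilities.decrement_stroke = 0.0
    for arm in ("tavi", "savr"):
        ev = ps.events.for_arm(arm)
        ev.thirty_day_ae_probs = {e: 0.0 for e in ev.thirty_day_ae_probs}
        if zero_morbidity:
            ev.monthly_aw_to_af = 0.0
            ev.monthly_aw_to_stroke = 0.0
            ev.monthly_af_to_stroke = 0.0
        if zero_costs:
            ev.monthly_rehosp_by_year = [0.0, 0.0, 0.0]
            ev.monthly_reintervention = 0.0
    if zero_costs:
        for f in list(type(ps.state_costs).model_fields):
            setattr(ps.state_costs, f, 0)
    ps.modifiers.hr_death_af = 1.0
    ps.modifiers.hr_death_stroke = 1.0
    return ps


class TestProbabilityTransforms:
    def test_annual_to_cycle_boundaries(self):
        assert annual_prob_to_cycle_prob(0.0, 12) == 0.0
        assert annual_prob_to_cycle_prob(1.0, 12) == 1.0

    def test_annual_to_cycle_round_trip(self):
        p = annual_prob_to_cycle_prob(0.12, 12)
        assert 1 - (1 - p) ** 12 == pytest.approx(0.12, abs=1e-12)

    def test_hazard_ratio_identity_and_closed_form(self):
        assert apply_hazard_ratio(0.37, 1.0) == pytest.approx(0.37)
        assert apply_hazard_ratio(0.01, 2.0) == pytest.approx(1 - 0.99**2)
        assert apply_hazard_ratio(0.0, 5.0) == 0.0
        assert apply_hazard_ratio(1.0, 0.3) == 1.0

    def test_hazard_ratio_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(0.1, 0.0)


class TestBackgroundMortality:
    def test_direct_lookup_single_sex(self, base_ps):
        lt = base_ps.life_table
        expected = annual_prob_to_cycle_prob(lt.annual_prob(75, "male"))
        assert background_mortality(lt, 75.0, 1.0, 0) == pytest.approx(expected)

    def test_sex_weighting_symmetry(self):
        lt = flat_life_table(0.08)
        only_male = background_mortality(lt, 70.0, 1.0, 0)
        mixed = background_mortality(lt, 70.0, 0.5, 0)
        assert mixed == pytest.approx(only_male)

    def test_twelve_cycles_compound_to_annual_entry(self):
        lt = flat_life_table(0.07)
        surv = 1.0
        for t in range(12):
            surv *= 1.0 - background_mortality(lt, 70.0, 1.0, t)
        assert 1 - surv == pytest.approx(0.07, abs=1e-12)

    def test_age_below_table_minimum_errors(self):
        lt = flat_life_table(0.05, min_age=70)
        with pytest.raises(Exception):
            background_mortality(lt, 50.0, 1.0, 0)


class TestTransitionMatrix:
    def test_no_risk_gives_identity(self, base_ps):
        ps = simple_ps(base_ps)
        P = build_transition_matrix(ps, "tavi", 0)
        assert np.allclose(P, np.eye(4))

    def test_unit_hazard_ratios_share_one_death_probability(self, base_ps):
        ps = simple_ps(base_ps, annual_mortality=0.10)
        P = build_transition_matrix(ps, "tavi", 0)
        assert P[0, 3] == pytest.approx(P[1, 3]) == pytest.approx(P[2, 3])

    def test_structural_zeros_and_row_sums(self, base_ps):
        n = 240
        P = transition_stack(base_ps, "savr", n)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)
        # stroke patients cannot recover; AF patients cannot return to well
        assert (P[:, 2, 0] == 0).all() and (P[:, 2, 1] == 0).all()
        assert (P[:, 1, 0] == 0).all()
        assert (P[:, 3, :3] == 0).all() and (P[:, 3, 3] == 1).all()


class TestRunCohort:
    def test_qaly_closed_form_one_year(self, base_ps):
        """Zero risk, norm 0.8, 12 undiscounted cycles -> exactly 0.8 QALY."""
        ps = simple_ps(base_ps, horizon_years=1.0)
        acute = run_decision_tree(ps, "tavi")
        trace = run_cohort(ps, "tavi", acute)
        assert trace.total_qaly(discounted=False) == pytest.approx(0.8, abs=1e-12)

    def test_discounted_costs_match_geometric_series(self, base_ps):
        """Constant monthly cost for year 1 equals the closed-form annuity."""
        ps = simple_ps(base_ps, horizon_years=1.0, discount=0.03, zero_costs=True)
        ps.state_costs.alive_well_year1_monthly = 1200
        acute = run_decision_tree(ps, "tavi")
        trace = run_cohort(ps, "tavi", acute)
        r = (1.03) ** (-1 / 12)
        expected = 1200 * (1 - r**12) / (1 - r)
        assert trace.total_cost(discounted=True) == pytest.approx(expected, abs=1e-10)

    def test_all_dead_seed_accrues_nothing(self, base_ps):
        ps = simple_ps(base_ps)
        probs = {e: 0.0 for e in ps.events.tavi.thirty_day_ae_probs}
        probs["death"] = 1.0
        ps.events.tavi.thirty_day_ae_probs = probs
        trace = run_cohort(ps, "tavi", run_decision_tree(ps, "tavi"))
        assert trace.total_cost(discounted=False) == 0.0
        assert trace.total_qaly(discounted=False) == 0.0
        assert (trace.occupancy[:, DD] == 1.0).all()

    def test_horizon_shorter_than_one_cycle_errors(self, base_ps):
        ps = base_ps.copy_deep()
        ps.settings.horizon_years = 0.01
        with pytest.raises(ValueError, match="horizon"):
            run_cohort(ps, "tavi", run_decision_tree(ps, "tavi"))

    def test_occupancy_conservation_and_dead_monotone(self, base_ps):
        for arm in ("tavi", "savr"):
            trace = run_cohort(base_ps, arm, run_decision_tree(base_ps, arm))
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
            assert (np.diff(trace.occupancy[:, DD]) >= -1e-12).all()

    def test_arm_symmetry_with_identical_inputs(self, equal_arm_ps):
        ps = equal_arm_ps
        traces = {
            arm: run_cohort(ps, arm, run_decision_tree(ps, arm)) for arm in ("tavi", "savr")
        }
        assert np.allclose(traces["tavi"].occupancy, traces["savr"].occupancy)
        assert traces["tavi"].total_cost() == pytest.approx(traces["savr"].total_cost())
        assert traces["tavi"].total_qaly() == pytest.approx(traces["savr"].total_qaly())

    def test_discounting_never_increases_accruals(self, base_ps):
        trace = run_cohort(base_ps, "tavi", run_decision_tree(base_ps, "tavi"))
        assert trace.total_cost(discounted=True) < trace.total_cost(discounted=False)
        assert trace.total_qaly(discounted=True) < trace.total_qaly(discounted=False)

    def test_af_mortality_hazard_monotonically_reduces_qalys(self, base_ps):
        qalys = []
        for hr in (1.0, 2.0, 4.0):
            ps = base_ps.copy_deep()
            ps.modifiers.hr_death_af = hr
            trace = run_cohort(ps, "savr", run_decision_tree(ps, "savr"))
            qalys.append(trace.total_qaly())
        assert qalys[0] > qalys[1] > qalys[2]

    def test_half_cycle_correction_lowers_outcomes_under_mortality(self, base_ps):
        ps = base_ps.copy_deep()
        ps.settings.half_cycle_correction = True
        hcc = run_cohort(ps, "tavi", run_decision_tree(ps, "tavi"))
        plain = run_cohort(base_ps, "tavi", run_decision_tree(base_ps, "tavi"))
        assert hcc.total_qaly() < plain.total_qaly()


class TestLifeYearsAndMedianSurvival:
    def test_immortal_cohort_life_years_equal_horizon(self, base_ps):
        ps = simple_ps(base_ps, horizon_years=10.0)
        trace = run_cohort(ps, "tavi", run_decision_tree(ps, "tavi"))
        assert life_years(trace) == pytest.approx(10.0, abs=1e-12)
        assert median_survival(trace) == math.inf

    def test_all_dead_gives_zero(self, base_ps):
        ps = simple_ps(base_ps)
        probs = {e: 0.0 for e in ps.events.tavi.thirty_day_ae_probs}
        probs["death"] = 1.0
        ps.events.tavi.thirty_day_ae_probs = probs
        trace = run_cohort(ps, "tavi", run_decision_tree(ps, "tavi"))
        assert life_years(trace) == 0.0

    def test_median_survival_closed_form(self, base_ps):
        """Constant monthly survival s with s^k = 0.5 -> median k/12 years."""
        k = 24
        s = 0.5 ** (1 / k)
        annual = 1 - s**12
        ps = simple_ps(base_ps, annual_mortality=annual, horizon_years=10.0)
        probs = {e: 0.0 for e in ps.events.tavi.thirty_day_ae_probs}
        probs["death"] = 1 - s  # first-month hazard matches the monthly one
        ps.events.tavi.thirty_day_ae_probs = probs
        trace = run_cohort(ps, "tavi", run_decision_tree(ps, "tavi"))
        assert median_survival(trace) == pytest.approx(k / 12, abs=1e-9)

    def test_discounted_life_years_below_undiscounted(self, base_ps):
        trace = run_cohort(base_ps, "tavi", run_decision_tree(base_ps, "tavi"))
        assert life_years(trace, discounted=True) < life_years(trace)


def test_discount_factors_hit_annual_rate_at_year_boundaries():
    df = discount_factors(0.03, 25)
    assert df[0] == 1.0
    assert df[12] == pytest.approx(1 / 1.03)
    assert df[24] == pytest.approx(1 / 1.03**2)
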