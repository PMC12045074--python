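"""DSA tornado, PSA/CEAC and the scenario engine."""

import math

import numpy as np
import pandas as pd
import pytest

import tavicea as tc
from tavicea.uncertainty import (
    DsaEntry,
    OverridePathError,
    PsaParam,
    PsaSpec,
    ScenarioNotRunnable,
    ceac,
    default_dsa_spec,
    default_psa_spec,
    get_by_path,
    load_scenarios,
    run_all_scenarios,
    run_dsa,
    run_psa,
    run_scenario,
    with_overrides,
)


class TestOverrides:
    def test_override_is_pure(self, base_ps):
        before = base_ps.model_dump(exclude={"life_table"})
        lt_before = base_ps.life_table.frame.copy()
        varied = with_overrides(base_ps, {"modifiers.hr_death_af": 3.0})
        assert varied.modifiers.hr_death_af == 3.0
        assert base_ps.model_dump(exclude={"life_table"}) == before
        pd.testing.assert_frame_equal(base_ps.life_table.frame, lt_before)

    def test_dict_and_per_arm_paths(self, base_ps):
        varied = with_overrides(
            base_ps,
            {
                "events.savr.thirty_day_ae_probs.new_af": 0.1,
                "procedure.index_procedure_cost.tavi": 111_111,
                "events.tavi.monthly_rehosp_by_year.1": 0.01,
            },
        )
        assert varied.events.savr.thirty_day_ae_probs["new_af"] == 0.1
        assert varied.procedure.index_procedure_cost.tavi == 111_111
        assert varied.events.tavi.monthly_rehosp_by_year[1] == 0.01

    def test_unresolvable_path_names_the_path(self, base_ps):
        with pytest.raises(OverridePathError, match="modifiers.hr_death_xx"):
            with_overrides(base_ps, {"modifiers.hr_death_xx": 1.0})


class TestDsa:
    def test_degenerate_range_has_zero_width(self, base_ps):
        base = float(get_by_path(base_ps, "modifiers.hr_death_af"))
        entries = run_dsa(
            base_ps, [DsaEntry(path="modifiers.hr_death_af", low=base, high=base)]
        )
        assert entries[0].nmb_width == pytest.approx(0.0, abs=1e-6)

    def test_wider_range_widens_the_bar(self, base_ps):
        path = "procedure.index_procedure_cost.tavi"
        base = float(get_by_path(base_ps, path))
        narrow = run_dsa(base_ps, [DsaEntry(path=path, low=base * 0.9, high=base * 1.1)])
        wide = run_dsa(base_ps, [DsaEntry(path=path, low=base * 0.8, high=base * 1.2)])
        assert wide[0].nmb_width > narrow[0].nmb_width

    def test_procedure_costs_dominate_when_given_widest_ranges(self, base_ps):
        """With the widest relative ranges, procedure costs rank on top."""
        spec = []
        for path in ("procedure.index_procedure_cost.tavi", "procedure.index_procedure_cost.savr"):
            b = float(get_by_path(base_ps, path))
            spec.append(DsaEntry(path=path, low=b * 0.8, high=b * 1.2))
        for path in ("state_costs.af_month2plus", "modifiers.hr_death_stroke", "utilities.decrement_af"):
            b = float(get_by_path(base_ps, path))
            spec.append(DsaEntry(path=path, low=b * 0.98, high=b * 1.02))
        entries = run_dsa(base_ps, spec)
        top_two = {entries[0].path, entries[1].path}
        assert top_two == {
            "procedure.index_procedure_cost.tavi",
            "procedure.index_procedure_cost.savr",
        }

    def test_invalid_override_yields_error_entry_and_continues(self, base_ps):
        spec = [
            DsaEntry(path="modifiers.hr_death_af", low=-2.0, high=2.0),
            DsaEntry(path="state_costs.af_month2plus", low=2000, high=2200),
        ]
        entries = run_dsa(base_ps, spec)
        by_path = {e.path: e for e in entries}
        assert by_path["modifiers.hr_death_af"].error is not None
        assert by_path["state_costs.af_month2plus"].error is None

    def test_default_spec_output_sorted_by_width(self, base_ps):
        entries = run_dsa(base_ps, default_dsa_spec(base_ps)[:6])
        widths = [e.nmb_width for e in entries if e.error is None]
        assert widths == sorted(widths, reverse=True)


@pytest.fixture(scope="module")
def small_psa(base_ps):
    spec = default_psa_spec(base_ps, draws=40, seed=123)
    return run_psa(base_ps, spec)


class TestPsa:
    def test_same_seed_reproduces_exactly(self, base_ps, small_psa):
        again = run_psa(base_ps, default_psa_spec(base_ps, draws=40, seed=123))
        pd.testing.assert_frame_equal(small_psa.draws, again.draws)

    def test_degenerate_distributions_reproduce_base_case(self, base_ps, base_result):
        spec = default_psa_spec(base_ps, draws=5, seed=1, cv=0.0)
        res = run_psa(base_ps, spec)
        assert np.allclose(res.draws["delta_cost"], base_result.delta_cost, atol=1e-6)
        assert np.allclose(res.draws["delta_qaly"], base_result.delta_qaly, atol=1e-12)

    def test_ceac_limits_match_quadrant_fractions(self, small_psa):
        draws = small_psa.draws
        lo = ceac(draws, [1e-9]).iloc[0]["prob_cost_effective"]
        hi = ceac(draws, [1e12]).iloc[0]["prob_cost_effective"]
        assert lo == pytest.approx(float((draws["delta_cost"] < 0).mean()))
        assert hi == pytest.approx(float((draws["delta_qaly"] > 0).mean()))

    def test_support_mismatch_rejected_before_drawing(self, base_ps):
        spec = PsaSpec(
            params=[PsaParam(path="modifiers.hr_death_af", family="beta")],
            draws=3,
            seed=0,
        )
        with pytest.raises(ValueError, match="beta"):
            run_psa(base_ps, spec)


class TestCeac:
    def test_single_draw_step_function_at_its_icer(self):
        draws = pd.DataFrame({"delta_cost": [50_000.0], "delta_qaly": [0.5]})
        curve = ceac(draws, [50_000, 99_999, 100_001, 500_000])
        assert list(curve["prob_cost_effective"]) == [0.0, 0.0, 1.0, 1.0]

    def test_all_dominant_draws_give_constant_one(self):
        draws = pd.DataFrame({"delta_cost": [-1.0, -2.0], "delta_qaly": [0.1, 0.2]})
        curve = ceac(draws, [0, 1e6])
        assert (curve["prob_cost_effective"] == 1.0).all()

    def test_monotone_when_all_draws_gain_qalys(self, small_psa):
        draws = small_psa.draws[small_psa.draws["delta_qaly"] > 0]
        curve = ceac(draws, list(np.linspace(0, 2e6, 21)))
        assert (np.diff(curve["prob_cost_effective"]) >= 0).all()

    def test_empty_grid_rejected(self, small_psa):
        with pytest.raises(ValueError):
            ceac(small_psa.draws, [])


class TestScenarios:
    def test_bundled_battery_has_sixteen(self):
        scenarios = load_scenarios()
        assert len(scenarios) == 16
        assert [s.id for s in scenarios] == [str(i) for i in range(1, 17)]

    def test_identity_scenario_equals_base(self, base_ps, base_result):
        from tavicea.uncertainty import ScenarioSpec

        res = run_scenario(base_ps, ScenarioSpec(id="0", label="identity"))
        assert res.delta_cost == pytest.approx(base_result.delta_cost)
        assert res.delta_qaly == pytest.approx(base_result.delta_qaly)

    def test_engine_is_pure(self, base_ps):
        before = base_ps.model_dump(exclude={"life_table"})
        for s in load_scenarios():
            if s.runnable:
                run_scenario(base_ps, s)
        assert base_ps.model_dump(exclude={"life_table"}) == before

    def test_structural_stubs_refuse_to_run(self, base_ps):
        stubs = [s for s in load_scenarios() if not s.runnable]
        assert {s.id for s in stubs} == {"1", "9"}
        with pytest.raises(ScenarioNotRunnable):
            run_scenario(base_ps, stubs[0])

    def test_removing_af_survival_penalty_reduces_qaly_gain(self, base_ps, base_result):
        """With SAVR's higher AF incidence, hr_death_af -> 1 shrinks dQALY."""
        s13 = next(s for s in load_scenarios() if s.id == "13")
        res = run_scenario(base_ps, s13)
        assert res.delta_qaly < base_result.delta_qaly

    def test_zero_af_state_costs_raise_incremental_cost(self, base_ps, base_result):
        """SAVR carries the higher AF occupancy, so dropping AF costs
        removes a SAVR-heavy cost and pushes dCost up."""
        s14 = next(s for s in load_scenarios() if s.id == "14")
        res = run_scenario(base_ps, s14)
        assert res.delta_cost > base_result.delta_cost

    def test_discount_ladder_orders_qaly_gain(self, base_ps):
        scenarios = {s.id: s for s in load_scenarios()}
        dq0 = run_scenario(base_ps, scenarios["10"]).delta_qaly
        dq5 = run_scenario(base_ps, scenarios["11"]).delta_qaly
        base = tc.run_base_case(base_ps).delta_qaly
        assert dq0 >= base >= dq5

    def test_finite_horizon_icers_converge_to_lifetime(self, base_ps, base_result):
        scenarios = {s.id: s for s in load_scenarios()}
        icer_5y = run_scenario(base_ps, scenarios["4"]).icer
        icer_30y = run_scenario(base_ps, scenarios["8"]).icer
        lifetime = base_result.icer
        assert abs(icer_30y - lifetime) < 0.1 * abs(icer_5y - lifetime)

    def test_kpp_costs_reproduce_quoted_totals(self, base_ps):
        from tavicea.acute import total_procedure_cost

        s16 = next(s for s in load_scenarios() if s.id == "16")
        varied = with_overrides(base_ps, s16.overrides)
        assert total_procedure_cost(varied.procedure, "tavi").total == 277_327
        assert total_procedure_cost(varied.procedure, "savr").total == 243_462

    def test_run_all_marks_stubs_skipped(self, base_ps):
        df = run_all_scenarios(base_ps)
        assert len(df) == 16
        assert set(df[df["status"] == "skipped"]["id"]) == {"1", "9"}
        assert (df[df["status"] == "ok"]["delta_cost"].notna()).all()
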