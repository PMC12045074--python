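"""Individual-level Monte Carlo simulator: the cohort engine's oracle.

Simulates n exchangeable individuals through the identical model — the same
day-30 allocation, the exact per-cycle transition matrices produced by the
cohort engine, and the same cost/QALY accrual rules — so that for any valid
parameter set the cohort expectations and the microsimulation means must
agree within Monte Carlo error.  Any divergence beyond ~3 standard errors
isolates a defect in the accrual logic of one of the two engines.

State paths are sampled; costs conditional on the path are accrued
deterministically (the per-cycle expected rehospitalisation, reintervention
and pacemaker-complication costs given the individual's state), and the
acute-phase expected cost enters as a constant, so means are directly
comparable with the cohort trace while path variability drives the standard
errors.  Within a cycle, events resolve death first, then stroke, then AF —
the same precedence the transition matrices encode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acute import AcutePhaseResult, STATES, run_decision_tree, total_procedure_cost
from .markov import (
    AW,
    AF,
    ST,
    DD,
    _utility_vectors,
    discount_factors,
    n_model_months,
    rehosp_monthly_prob,
    transition_stack,
)
from .params import Arm, ParameterSet


@dataclass(frozen=True)
class MicrosimSummary:
    arm: str
    n: int
    mean_cost: float
    se_cost: float
    mean_qaly: float
    se_qaly: float
    mean_life_years: float
    se_life_years: float
    median_survival_years: float
    person_months_by_state: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "arm": self.arm,
            "n": self.n,
            "mean_cost": self.mean_cost,
            "se_cost": self.se_cost,
            "mean_qaly": self.mean_qaly,
            "se_qaly": self.se_qaly,
            "mean_life_years": self.mean_life_years,
            "se_life_years": self.se_life_years,
            "median_survival_years": self.median_survival_years,
            "person_months_by_state": self.person_months_by_state,
        }


def simulate_cohort(
    ps: ParameterSet,
    arm: Arm,
    n: int,
    seed: int,
    acute: AcutePhaseResult | None = None,
) -> MicrosimSummary:
    """Simulate ``n`` individuals through decision tree + Markov phases."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if acute is None:
        acute = run_decision_tree(ps, arm)
    n_cycles = n_model_months(ps)
    P = transition_stack(ps, arm, n_cycles)
    cumP = P.cumsum(axis=2)
    ev = ps.events.for_arm(arm)
    sc = ps.state_costs

    # per-cycle deterministic inputs shared with the cohort engine
    u_aw, u_af, u_st = _utility_vectors(ps, n_cycles)
    util = np.stack([u_aw, u_af, u_st, np.zeros(n_cycles)], axis=1)  # (n_cycles, 4)
    df_c = discount_factors(ps.settings.annual_discount_rate_costs, n_cycles)
    df_o = discount_factors(ps.settings.annual_discount_rate_outcomes, n_cycles)
    rehosp_exp = np.array(
        [rehosp_monthly_prob(ev, t) * sc.rehospitalisation_cost for t in range(n_cycles)]
    )
    p_reint = ev.monthly_reintervention * (
        ps.modifiers.rr_reintervention if arm == "tavi" else 1.0
    )
    reint_exp = p_reint * total_procedure_cost(ps.procedure, arm).total
    aw_monthly = np.where(
        np.arange(n_cycles) < 12, sc.alive_well_year1_monthly, sc.alive_well_year2plus_monthly
    )
    month1_cost = np.array(
        [0.0, sc.af_month1, sc.stroke_month1 + sc.caregiver_stroke_month1, 0.0]
    )
    month2_cost = np.array(
        [0.0, sc.af_month2plus, sc.stroke_month2plus + sc.caregiver_stroke_month2plus, 0.0]
    )

    # day-30 allocation and pacemaker carrier status
    p0 = np.array([acute.day30_distribution[s] for s in STATES])
    state = rng.choice(4, size=n, p=p0 / p0.sum())
    carrier = rng.random(n) < acute.pacemaker_carrier_fraction

    # expected acute cost (procedure + toggled AE costs + 30-day death cost)
    # enters as a constant, matching the cohort report's acute components
    cost = np.full(n, acute.acute_cost_total + acute.acute_cost_components["death"])
    qaly = np.zeros(n)
    ly = np.zeros(n)
    person_months = np.zeros(4)
    death_cycle = np.full(n, -1, dtype=int)
    death_cycle[state == DD] = 0

    for t in range(n_cycles):
        if t > 0:
            # advance survivors through the cycle-(t-1) matrix
            alive_idx = np.flatnonzero(state != DD)
            if alive_idx.size:
                u = rng.random(alive_idx.size)
                rows = cumP[t - 1, state[alive_idx]]  # (m, 4)
                new_state = (u[:, None] > rows).sum(axis=1)
                entered = new_state != state[alive_idx]
                died = new_state == DD
                cost[alive_idx[died]] += df_c[t] * sc.death_cost
                death_cycle[alive_idx[died]] = t
                # month-1 state cost for fresh AF/stroke entrants
                m1 = alive_idx[entered & ~died]
                cost[m1] += df_c[t] * month1_cost[new_state[entered & ~died]]
                stay = alive_idx[~entered]
                cost[stay] += df_c[t] * month2_cost[state[stay]]
                state[alive_idx] = new_state
        else:
            # first model month: everyone in an AF/stroke seed state is a
            # fresh entrant (the event occurred within the first 30 days)
            living = state != DD
            cost[living] += df_c[0] * month1_cost[state[living]]

        living = state != DD
        person_months += np.bincount(state, minlength=4)
        ly[living] += 1.0 / 12.0
        qaly += df_o[t] * util[t, state] / 12.0
        cost[living & (state == AW)] += df_c[t] * aw_monthly[t]
        if t > 0:
            cost[living] += df_c[t] * (rehosp_exp[t] + reint_exp)
            cost[living & carrier] += df_c[t] * sc.pacemaker_complication_monthly

    # empirical median survival: death time of the median individual
    # (individuals alive at the horizon contribute censored times = inf)
    times = np.where(death_cycle >= 0, death_cycle / 12.0, np.inf)
    median = float(np.median(times))

    return MicrosimSummary(
        arm=arm,
        n=n,
        mean_cost=float(cost.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_qaly=float(qaly.mean()),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        mean_life_years=float(ly.mean()),
        se_life_years=float(ly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        median_survival_years=median,
        person_months_by_state={s: float(person_months[i] / n) for i, s in enumerate(STATES)},
    )
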