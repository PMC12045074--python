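"""Acute-phase decision tree: procedure cost roll-up and 30-day events.

The first model stage covers the index procedure and the first 30 days.
Expected procedure cost per arm is index cost + rehabilitation component
(unit cost x rate) + pacemaker-insertion component (unit cost x rate, or a
supplied expected-cost override).  30-day adverse events either allocate the
cohort to its day-30 Markov state (death, disabling stroke, new AF — treated
as mutually exclusive branches) or incur a one-off cost and return the
patient to "alive and well" (MI, TIA, bleeding, AKI, non-disabling stroke).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .params import (
    Arm,
    COSTED_AE,
    ParameterSet,
    ProcedureCostInputs,
)

#: Markov state order used throughout the package.
STATES = ("alive_well", "treated_af", "disabling_stroke", "dead")


def round_sek(x: float) -> int:
    """Round to whole SEK, half away from zero (spreadsheet convention)."""
    import math

    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def expected_component_cost(unit_cost: float, rate: float) -> float:
    """Expected cost of a per-procedure component: ``unit_cost * rate``.

    The unrounded value is returned; reporting rounds to whole SEK.
    """
    if unit_cost < 0:
        raise ValueError("unit_cost must be >= 0")
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    return unit_cost * rate


@dataclass(frozen=True)
class ProcedureCostBreakdown:
    arm: str
    index_procedure: float
    rehabilitation: float
    pacemaker_insertion: float

    @property
    def total(self) -> float:
        return self.index_procedure + self.rehabilitation + self.pacemaker_insertion

    def rounded(self) -> dict[str, int]:
        """Table-2-shaped rows: components rounded, total of rounded rows."""
        rows = {
            "Procedure": round_sek(self.index_procedure),
            "Rehabilitation": round_sek(self.rehabilitation),
            "Pacemaker insertion": round_sek(self.pacemaker_insertion),
        }
        rows["Total procedure costs"] = sum(rows.values())
        return rows


def total_procedure_cost(procedure: ProcedureCostInputs, arm: Arm) -> ProcedureCostBreakdown:
    """Expected per-patient procedure cost with its component breakdown."""
    rehab = expected_component_cost(procedure.rehab_unit_cost, procedure.rehab_rate.for_arm(arm))
    override = procedure.pacemaker_expected_cost_override.for_arm(arm)
    if override is not None:
        pacemaker = float(override)
    else:
        pacemaker = expected_component_cost(
            procedure.pacemaker_unit_cost, procedure.pacemaker_rate.for_arm(arm)
        )
    return ProcedureCostBreakdown(
        arm=arm,
        index_procedure=float(procedure.index_procedure_cost.for_arm(arm)),
        rehabilitation=rehab,
        pacemaker_insertion=pacemaker,
    )


@dataclass(frozen=True)
class AcutePhaseResult:
    """Day-30 state allocation plus acute costs and first-month outcomes."""

    arm: str
    day30_distribution: dict[str, float]
    acute_cost_total: float
    acute_cost_components: dict[str, float] = field(default_factory=dict)
    pacemaker_carrier_fraction: float = 0.0
    #: QALYs and life years accrued during the first model month, valued at
    #: the day-30 state distribution (30-day deaths contribute neither).
    acute_qaly: float = 0.0
    acute_life_years: float = 0.0

    def __post_init__(self) -> None:
        total = sum(self.day30_distribution.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"day-30 distribution sums to {total}, not 1")
        if any(p < -1e-15 for p in self.day30_distribution.values()):
            raise ValueError("day-30 distribution has a negative entry")
        if self.acute_cost_total < 0:
            raise ValueError("acute cost must be >= 0")


def run_decision_tree(ps: ParameterSet, arm: Arm) -> AcutePhaseResult:
    """Evaluate the 30-day decision tree for one arm.

    The day-30 distribution over the four Markov states is assembled from the
    30-day death, disabling-stroke and new-AF probabilities (remainder goes
    to "alive and well").  One-off AE costs enter ``acute_cost_total`` only
    when ``settings.include_acute_ae_costs`` is set; with the toggle off the
    total reduces exactly to the expected procedure cost.  30-day deaths
    accrue the death cost once, carried as the separate ``death`` component
    (reported under the year-1 death-cost category).
    """
    ev = ps.events.for_arm(arm)
    probs = ev.thirty_day_ae_probs
    p_death = probs.get("death", 0.0)
    p_stroke = probs.get("disabling_stroke", 0.0)
    p_af = probs.get("new_af", 0.0)
    branch_sum = p_death + p_stroke + p_af
    if branch_sum > 1.0 + 1e-12:
        raise ValueError(
            f"{arm}: mutually exclusive 30-day branch probabilities sum to {branch_sum} > 1"
        )
    dist = {
        "alive_well": max(1.0 - branch_sum, 0.0),
        "treated_af": p_af,
        "disabling_stroke": p_stroke,
        "dead": p_death,
    }

    breakdown = total_procedure_cost(ps.procedure, arm)
    components: dict[str, float] = {
        "index_procedure": breakdown.index_procedure,
        "rehabilitation": breakdown.rehabilitation,
        "pacemaker_insertion": breakdown.pacemaker_insertion,
        "acute_aes": 0.0,
        "death": p_death * ps.state_costs.death_cost,
    }
    if ps.settings.include_acute_ae_costs:
        components["acute_aes"] = sum(
            probs.get(name, 0.0) * ev.ae_costs.get(name, 0) for name in COSTED_AE
        )
    total = breakdown.total + components["acute_aes"]

    # first-month utility/survival valued at the day-30 allocation
    age = ps.settings.start_age_years
    pm = ps.settings.proportion_male
    qaly = sum(
        dist[s] * ps.utilities.state_utility(s, age, pm) / 12.0
        for s in STATES
        if s != "dead"
    )
    life_years = (1.0 - dist["dead"]) / 12.0

    return AcutePhaseResult(
        arm=arm,
        day30_distribution=dist,
        acute_cost_total=total,
        acute_cost_components=components,
        pacemaker_carrier_fraction=probs.get("pacemaker", 0.0),
        acute_qaly=qaly,
        acute_life_years=life_years,
    )
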