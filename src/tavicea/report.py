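"""Incremental cost-effectiveness reporting.

Combines the two arms' acute-phase and cohort results into the standard
cost-utility report: per-arm lifetime costs and QALYs, undiscounted life
years, median survival, a cost breakdown at one year and over the lifetime,
and the incremental column with ICER, net monetary benefit
(NMB = WTP x dQALY - dCost) and net health benefit (NHB = dQALY - dCost/WTP).

Dominance follows the cost-effectiveness-plane quadrant convention: a bare
ratio is reported only when it is interpretable; "dominant" (cheaper, more
effective), "dominated" (dearer, less effective) and "undefined"
(dQALY = 0) are labels, never exceptions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .acute import AcutePhaseResult, round_sek
from .markov import CohortTrace, life_years, median_survival
from .params import ModelSettings

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"

#: Table row labels for the per-category cost breakdown.
BREAKDOWN_ROWS = (
    "Index hospitalisation",
    "Rehabilitation",
    "Acute phase costs",
    "30-day AE costs",
    "Costs of pacemaker complications",
    "Costs of hospitalizations",
    "Re-intervention costs",
    "Alive & well health state costs",
    "Treated AF health state costs",
    "Disabling stroke costs",
    "Death costs",
)


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """ICER or a dominance label, by cost-effectiveness-plane quadrant."""
    if delta_qaly == 0:
        return UNDEFINED
    if delta_qaly > 0:
        if delta_cost <= 0:
            return DOMINANT if delta_cost < 0 else 0.0
        return delta_cost / delta_qaly
    if delta_cost >= 0:
        return DOMINATED
    # southwest quadrant: savings per QALY forgone
    return delta_cost / delta_qaly


def net_benefit(delta_cost: float, delta_qaly: float, wtp: float) -> tuple[float, float]:
    """(NMB, NHB) at willingness-to-pay ``wtp`` per QALY."""
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    nmb = wtp * delta_qaly - delta_cost
    nhb = delta_qaly - delta_cost / wtp
    return nmb, nhb


def incremental_column(arm_a: Mapping[str, float], arm_b: Mapping[str, float]) -> dict[str, float]:
    """Exact differences arm_a - arm_b over matching summary entries."""
    missing = set(arm_a) ^ set(arm_b)
    if missing:
        raise ValueError(f"mismatched summary entries: {sorted(missing)}")
    return {k: arm_a[k] - arm_b[k] for k in arm_a}


@dataclass
class ArmSummary:
    arm: str
    lifetime_cost: float
    lifetime_qaly: float
    life_years_undiscounted: float
    median_survival_years: float  # inf => beyond horizon
    breakdown_1y: dict[str, float]
    breakdown_lifetime_additional: dict[str, float]
    total_1y: float
    additional_lifetime: float


@dataclass
class IncrementalResult:
    """Per-arm summaries plus the incremental cost-effectiveness column."""

    arms: dict[str, ArmSummary]
    delta_cost: float
    delta_qaly: float
    delta_life_years: float
    delta_median_survival: float
    icer: float | str
    nmb: float
    nhb: float
    wtp: float
    scenario_id: str | None = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        a, b = self.arms["tavi"], self.arms["savr"]

        def ms(v: float) -> object:
            return ">horizon" if math.isinf(v) else round(v, 2)

        rows: list[tuple[str, object, object, object]] = [
            ("Cost per patient", round_sek(a.lifetime_cost), round_sek(b.lifetime_cost), round_sek(self.delta_cost)),
            ("Life year gained (undiscounted)", round(a.life_years_undiscounted, 2), round(b.life_years_undiscounted, 2), round(self.delta_life_years, 2)),
            ("Median survival (years)", ms(a.median_survival_years), ms(b.median_survival_years), round(self.delta_median_survival, 2)),
            ("QALYs per patient", round(a.lifetime_qaly, 2), round(b.lifetime_qaly, 2), round(self.delta_qaly, 2)),
            ("Incremental cost effectiveness ratio (ICER)", "", "", self.icer if isinstance(self.icer, str) else round_sek(self.icer)),
            ("Incremental net monetary benefit (NMB)", "", "", round_sek(self.nmb)),
            ("Incremental net health benefit (NHB)", "", "", round(self.nhb, 2)),
        ]
        for label in ("Index hospitalisation", "Rehabilitation", "Acute phase costs"):
            rows.append((label, round_sek(a.breakdown_1y[label]), round_sek(b.breakdown_1y[label]), round_sek(a.breakdown_1y[label] - b.breakdown_1y[label])))
        for label in BREAKDOWN_ROWS[3:]:
            rows.append((label, round_sek(a.breakdown_1y[label]), round_sek(b.breakdown_1y[label]), round_sek(a.breakdown_1y[label] - b.breakdown_1y[label])))
        rows.append(("Total costs at 1 year", round_sek(a.total_1y), round_sek(b.total_1y), round_sek(a.total_1y - b.total_1y)))
        for label in BREAKDOWN_ROWS[3:]:
            rows.append((f"{label} (lifetime additional)", round_sek(a.breakdown_lifetime_additional[label]), round_sek(b.breakdown_lifetime_additional[label]), round_sek(a.breakdown_lifetime_additional[label] - b.breakdown_lifetime_additional[label])))
        rows.append(("Additional lifetime costs", round_sek(a.additional_lifetime), round_sek(b.additional_lifetime), round_sek(a.additional_lifetime - b.additional_lifetime)))
        rows.append(("Total lifetime costs", round_sek(a.lifetime_cost), round_sek(b.lifetime_cost), round_sek(self.delta_cost)))
        return pd.DataFrame(rows, columns=["Summary results", "TAVI with SAPIEN 3", "SAVR", "Incremental"])

    def to_json(self) -> str:
        df = self.to_frame()
        return json.dumps(
            {
                "scenario_id": self.scenario_id,
                "wtp_per_qaly": self.wtp,
                "rows": df.to_dict(orient="records"),
            },
            indent=2,
        )


def _arm_summary(arm: str, trace: CohortTrace, acute: AcutePhaseResult) -> ArmSummary:
    year1 = slice(0, 12)
    later = slice(12, None)
    cat_1y = trace.cost_by_category(discounted=True, cycles=year1)
    cat_lt = trace.cost_by_category(discounted=True, cycles=later)
    comp = acute.acute_cost_components

    acute_phase = comp["index_procedure"] + comp["rehabilitation"] + comp["pacemaker_insertion"]
    breakdown_1y = {
        "Index hospitalisation": comp["index_procedure"] + comp["pacemaker_insertion"],
        "Rehabilitation": comp["rehabilitation"],
        "Acute phase costs": acute_phase,
        "30-day AE costs": comp["acute_aes"],
        "Costs of pacemaker complications": cat_1y["pacemaker_complications"],
        "Costs of hospitalizations": cat_1y["rehospitalisation"],
        "Re-intervention costs": cat_1y["reintervention"],
        "Alive & well health state costs": cat_1y["alive_well"],
        "Treated AF health state costs": cat_1y["treated_af"],
        "Disabling stroke costs": cat_1y["disabling_stroke"],
        "Death costs": comp["death"] + cat_1y["death"],
    }
    breakdown_lt = {
        "30-day AE costs": 0.0,
        "Costs of pacemaker complications": cat_lt["pacemaker_complications"],
        "Costs of hospitalizations": cat_lt["rehospitalisation"],
        "Re-intervention costs": cat_lt["reintervention"],
        "Alive & well health state costs": cat_lt["alive_well"],
        "Treated AF health state costs": cat_lt["treated_af"],
        "Disabling stroke costs": cat_lt["disabling_stroke"],
        "Death costs": cat_lt["death"],
    }
    total_1y = sum(breakdown_1y.values()) - breakdown_1y["Index hospitalisation"] - breakdown_1y["Rehabilitation"]
    additional_lifetime = sum(breakdown_lt.values())
    lifetime_cost = total_1y + additional_lifetime
    lifetime_qaly = trace.total_qaly(discounted=True)
    return ArmSummary(
        arm=arm,
        lifetime_cost=lifetime_cost,
        lifetime_qaly=lifetime_qaly,
        life_years_undiscounted=life_years(trace, discounted=False),
        median_survival_years=median_survival(trace),
        breakdown_1y=breakdown_1y,
        breakdown_lifetime_additional=breakdown_lt,
        total_1y=total_1y,
        additional_lifetime=additional_lifetime,
    )


def build_report(
    trace_tavi: CohortTrace,
    trace_savr: CohortTrace,
    acute_tavi: AcutePhaseResult,
    acute_savr: AcutePhaseResult,
    settings: ModelSettings,
) -> IncrementalResult:
    """Assemble the incremental cost-effectiveness report for TAVI vs SAVR."""
    if trace_tavi.n_cycles != trace_savr.n_cycles:
        raise ValueError("arms were run on mismatched horizons")
    a = _arm_summary("tavi", trace_tavi, acute_tavi)
    b = _arm_summary("savr", trace_savr, acute_savr)

    # internal additivity check on unrounded values
    for s in (a, b):
        comps_1y = sum(v for k, v in s.breakdown_1y.items() if k not in ("Index hospitalisation", "Rehabilitation"))
        assert abs(comps_1y - s.total_1y) < 1e-6
        assert abs(sum(s.breakdown_lifetime_additional.values()) - s.additional_lifetime) < 1e-6
        assert abs(s.total_1y + s.additional_lifetime - s.lifetime_cost) < 1e-6

    delta_cost = a.lifetime_cost - b.lifetime_cost
    delta_qaly = a.lifetime_qaly - b.lifetime_qaly
    ratio = icer(delta_cost, delta_qaly)
    nmb, nhb = net_benefit(delta_cost, delta_qaly, settings.wtp_per_qaly)
    d_ms = (
        a.median_survival_years - b.median_survival_years
        if math.isfinite(a.median_survival_years) and math.isfinite(b.median_survival_years)
        else math.nan
    )
    return IncrementalResult(
        arms={"tavi": a, "savr": b},
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        delta_life_years=a.life_years_undiscounted - b.life_years_undiscounted,
        delta_median_survival=d_ms,
        icer=ratio,
        nmb=nmb,
        nhb=nhb,
        wtp=settings.wtp_per_qaly,
    )


def run_base_case(ps) -> IncrementalResult:
    """Run the full two-arm pipeline (decision tree + cohort) on one
    parameter set and return the incremental report."""
    from .acute import run_decision_tree
    from .markov import run_cohort

    acute = {arm: run_decision_tree(ps, arm) for arm in ("tavi", "savr")}
    traces = {arm: run_cohort(ps, arm, acute[arm]) for arm in ("tavi", "savr")}
    return build_report(traces["tavi"], traces["savr"], acute["tavi"], acute["savr"], ps.settings)
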