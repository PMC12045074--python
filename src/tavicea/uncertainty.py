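"""Sensitivity and scenario analyses.

* Univariate deterministic sensitivity analysis (DSA): each parameter is set
  to its low and high value in turn (all others at base), the full pipeline
  is rerun, and entries are ranked by the width of the net-monetary-benefit
  interval — the tornado ordering.
* Probabilistic sensitivity analysis (PSA): all parameters are drawn jointly
  and independently from distributions matched to their support (beta for
  probabilities and utilities, gamma for costs, lognormal for hazard
  ratios), the pipeline is evaluated per draw, and the draw cloud yields the
  cost-effectiveness plane and acceptability curve (CEAC: the fraction of
  draws with positive net benefit at each willingness-to-pay).
* Scenario engine: declarative overrides of parameter-set paths (dotted
  paths such as ``modifiers.hr_death_af``), applied to a deep copy — the
  base parameter set is never touched.

Where no published variance exists, distributions are moment-matched from
the base value with an assumed coefficient of variation (default 0.2), and
DSA ranges default to +/-20% of base; both are declared assumptions.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .params import ParameterSet, PerArm, validate_parameter_set
from .report import IncrementalResult, net_benefit, run_base_case

DEFAULT_CV = 0.2

#: WTP grid for the acceptability curve (SEK/QALY); includes the 500,000 and
#: 1,000,000 SEK thresholds discussed for the Swedish setting.
DEFAULT_WTP_GRID = tuple(np.arange(0, 2_000_001, 50_000))


# ---------------------------------------------------------------------------
# parameter-path plumbing


class OverridePathError(KeyError):
    pass


def _resolve_parent(ps: ParameterSet, path: str):
    parts = path.split(".")
    obj = ps
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise OverridePathError(f"cannot resolve {path!r} (no key {part!r})")
            obj = obj[part]
        elif isinstance(obj, list):
            try:
                obj = obj[int(part)]
            except (ValueError, IndexError) as exc:
                raise OverridePathError(f"cannot resolve {path!r} (bad index {part!r})") from exc
        else:
            if not hasattr(obj, part):
                raise OverridePathError(f"cannot resolve {path!r} (no field {part!r})")
            obj = getattr(obj, part)
    return obj, parts[-1]


def get_by_path(ps: ParameterSet, path: str):
    parent, leaf = _resolve_parent(ps, path)
    if isinstance(parent, dict):
        if leaf not in parent:
            raise OverridePathError(f"cannot resolve {path!r} (no key {leaf!r})")
        return parent[leaf]
    if isinstance(parent, list):
        return parent[int(leaf)]
    if not hasattr(parent, leaf):
        raise OverridePathError(f"cannot resolve {path!r} (no field {leaf!r})")
    return getattr(parent, leaf)


def with_overrides(ps: ParameterSet, overrides: dict[str, object]) -> ParameterSet:
    """A deep copy of ``ps`` with each dotted path replaced; pure."""
    out = ps.copy_deep()
    for path, value in overrides.items():
        parent, leaf = _resolve_parent(out, path)
        current = get_by_path(out, path)
        if isinstance(current, int) and not isinstance(current, bool) and isinstance(value, float):
            value = int(round(value))  # monetary fields are whole SEK
        if isinstance(parent, dict):
            parent[leaf] = value
        elif isinstance(parent, list):
            parent[int(leaf)] = value
        else:
            if not hasattr(parent, leaf):
                raise OverridePathError(f"cannot resolve {path!r} (no field {leaf!r})")
            setattr(parent, leaf, value)
    return out


# ---------------------------------------------------------------------------
# deterministic sensitivity analysis


class DsaEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: str
    low: float
    high: float
    note: str = "plausible range"


@dataclass
class TornadoEntry:
    path: str
    icer_low: float | str
    icer_high: float | str
    nmb_low: float
    nmb_high: float
    note: str
    error: Optional[str] = None

    @property
    def nmb_width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def default_dsa_spec(ps: ParameterSet, rel: float = 0.2) -> list[DsaEntry]:
    """+/-``rel`` ranges around base for the influential scalar inputs."""
    paths = [
        "procedure.index_procedure_cost.tavi",
        "procedure.index_procedure_cost.savr",
        "state_costs.af_month1",
        "state_costs.af_month2plus",
        "state_costs.stroke_month1",
        "state_costs.stroke_month2plus",
        "state_costs.rehospitalisation_cost",
        "state_costs.pacemaker_complication_monthly",
        "modifiers.hr_death_af",
        "modifiers.hr_death_stroke",
        "utilities.decrement_af",
        "utilities.decrement_stroke",
        "events.tavi.thirty_day_ae_probs.new_af",
        "events.savr.thirty_day_ae_probs.new_af",
        "events.tavi.monthly_aw_to_stroke",
        "events.savr.monthly_aw_to_stroke",
    ]
    spec = []
    for p in paths:
        base = float(get_by_path(ps, p))
        lo, hi = base * (1 - rel), base * (1 + rel)
        if "probs" in p or "monthly" in p or p.startswith("utilities"):
            hi = min(hi, 1.0)
        spec.append(DsaEntry(path=p, low=lo, high=hi, note="plausible range (+/-20%)"))
    return spec


def run_dsa(ps: ParameterSet, spec: Sequence[DsaEntry], top_k: int | None = None) -> list[TornadoEntry]:
    """Tornado entries sorted by descending NMB width.

    An override that violates the input invariants yields a per-parameter
    error entry; the analysis continues.
    """
    base_nmb = None
    entries: list[TornadoEntry] = []
    for e in spec:
        results = {}
        err = None
        for bound, value in (("low", e.low), ("high", e.high)):
            try:
                varied = with_overrides(ps, {e.path: value})
                violations = validate_parameter_set(varied)
                if violations:
                    raise ValueError(str(violations[0]))
                results[bound] = run_base_case(varied)
            except (ValueError, OverridePathError) as exc:
                err = f"{bound}: {exc}"
                break
        if err is not None:
            entries.append(TornadoEntry(e.path, math.nan, math.nan, math.nan, math.nan, e.note, error=err))
            continue
        lo, hi = results["low"], results["high"]
        entries.append(
            TornadoEntry(
                path=e.path,
                icer_low=lo.icer,
                icer_high=hi.icer,
                nmb_low=lo.nmb,
                nmb_high=hi.nmb,
                note=e.note,
            )
        )
    ok = [t for t in entries if t.error is None]
    bad = [t for t in entries if t.error is not None]
    ok.sort(key=lambda t: t.nmb_width, reverse=True)
    out = ok + bad
    return out[:top_k] if top_k else out


def tornado_frame(entries: Iterable[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": t.path,
                "icer_low": t.icer_low,
                "icer_high": t.icer_high,
                "nmb_low": t.nmb_low,
                "nmb_high": t.nmb_high,
                "nmb_width": t.nmb_width,
                "note": t.note,
                "error": t.error or "",
            }
            for t in entries
        ]
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


class PsaParam(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: str
    family: str  # beta | gamma | lognormal
    cv: float = DEFAULT_CV


class PsaSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    params: list[PsaParam]
    draws: int
    seed: int

    def validate_support(self, ps: ParameterSet) -> None:
        for p in self.params:
            base = float(get_by_path(ps, p.path))
            if p.family == "beta" and not (0.0 <= base <= 1.0):
                raise ValueError(f"{p.path}: beta family needs base in [0,1], got {base}")
            if p.family in ("gamma", "lognormal") and base < 0:
                raise ValueError(f"{p.path}: {p.family} family needs base >= 0, got {base}")
            if p.family not in ("beta", "gamma", "lognormal"):
                raise ValueError(f"{p.path}: unknown family {p.family!r}")
        if self.draws < 1:
            raise ValueError("draws must be >= 1")


def default_psa_spec(ps: ParameterSet, draws: int | None = None, seed: int | None = None, cv: float = DEFAULT_CV) -> PsaSpec:
    """Distributions matched to parameter support with a common CV."""
    params: list[PsaParam] = []
    for arm in ("tavi", "savr"):
        for ev in ("death", "disabling_stroke", "new_af"):
            params.append(PsaParam(path=f"events.{arm}.thirty_day_ae_probs.{ev}", family="beta", cv=cv))
        for name in ("monthly_aw_to_af", "monthly_aw_to_stroke", "monthly_af_to_stroke"):
            params.append(PsaParam(path=f"events.{arm}.{name}", family="beta", cv=cv))
        for i in range(3):
            params.append(PsaParam(path=f"events.{arm}.monthly_rehosp_by_year.{i}", family="beta", cv=cv))
        params.append(PsaParam(path=f"procedure.index_procedure_cost.{arm}", family="gamma", cv=cv))
    for name in ("af_month1", "af_month2plus", "stroke_month1", "stroke_month2plus", "rehospitalisation_cost", "pacemaker_complication_monthly", "death_cost"):
        params.append(PsaParam(path=f"state_costs.{name}", family="gamma", cv=cv))
    for name in ("hr_death_af", "hr_death_stroke"):
        params.append(PsaParam(path=f"modifiers.{name}", family="lognormal", cv=cv))
    for name in ("decrement_af", "decrement_stroke"):
        params.append(PsaParam(path=f"utilities.{name}", family="beta", cv=cv))
    return PsaSpec(
        params=params,
        draws=draws if draws is not None else ps.settings.psa_draws,
        seed=seed if seed is not None else ps.settings.random_seed,
    )


def _draw(rng: np.random.Generator, family: str, mean: float, cv: float) -> float:
    """One moment-matched draw; a zero CV or a degenerate mean is a point mass."""
    if cv == 0 or mean == 0:
        return mean
    sd = cv * mean
    if family == "beta":
        if mean >= 1.0:
            return 1.0
        var = min(sd**2, mean * (1 - mean) * 0.999)
        nu = mean * (1 - mean) / var - 1.0
        a, b = mean * nu, (1 - mean) * nu
        return float(rng.beta(a, b))
    if family == "gamma":
        shape = 1.0 / cv**2
        scale = mean * cv**2
        return float(rng.gamma(shape, scale))
    if family == "lognormal":
        sigma2 = math.log(1 + cv**2)
        mu = math.log(mean) - sigma2 / 2
        return float(rng.lognormal(mu, math.sqrt(sigma2)))
    raise ValueError(f"unknown family {family!r}")


@dataclass
class PsaResult:
    draws: pd.DataFrame  # columns: delta_cost, delta_qaly
    seed: int
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID

    def ceac(self, wtp_grid: Sequence[float] | None = None) -> pd.DataFrame:
        grid = tuple(wtp_grid) if wtp_grid is not None else self.wtp_grid
        return ceac(self.draws, grid)

    def prob_cost_effective(self, wtp: float) -> float:
        nb = wtp * self.draws["delta_qaly"] - self.draws["delta_cost"]
        return float((nb > 0).mean())

    def mean_delta_cost(self) -> float:
        return float(self.draws["delta_cost"].mean())

    def mean_delta_qaly(self) -> float:
        return float(self.draws["delta_qaly"].mean())


def ceac(draws: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Fraction of draws with positive net benefit at each WTP."""
    if len(wtp_grid) == 0:
        raise ValueError("empty WTP grid")
    if len(draws) == 0:
        raise ValueError("need at least one draw")
    dq = draws["delta_qaly"].to_numpy()
    dc = draws["delta_cost"].to_numpy()
    rows = [(w, float((w * dq - dc > 0).mean())) for w in wtp_grid]
    return pd.DataFrame(rows, columns=["wtp", "prob_cost_effective"])


def run_psa(ps: ParameterSet, spec: PsaSpec | None = None) -> PsaResult:
    """Monte Carlo over the parameter distributions; reproducible by seed."""
    if spec is None:
        spec = default_psa_spec(ps)
    spec.validate_support(ps)
    rng = np.random.default_rng(spec.seed)
    bases = {p.path: float(get_by_path(ps, p.path)) for p in spec.params}
    records = []
    for _ in range(spec.draws):
        overrides = {p.path: _draw(rng, p.family, bases[p.path], p.cv) for p in spec.params}
        varied = with_overrides(ps, overrides)
        res = run_base_case(varied)
        records.append((res.delta_cost, res.delta_qaly))
    df = pd.DataFrame(records, columns=["delta_cost", "delta_qaly"])
    return PsaResult(draws=df, seed=spec.seed)


# ---------------------------------------------------------------------------
# scenario engine


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    label: str
    overrides: dict[str, object] = {}
    runnable: bool = True
    note: str = ""


class ScenarioNotRunnable(RuntimeError):
    pass


def load_scenarios(path=None) -> list[ScenarioSpec]:
    """The bundled scenario battery (or a user-supplied scenario file)."""
    if path is None:
        text = (resources.files("tavicea") / "data" / "scenarios.yaml").read_text()
    else:
        from pathlib import Path

        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return [ScenarioSpec(**s) for s in doc["scenarios"]]


def run_scenario(ps: ParameterSet, scenario: ScenarioSpec) -> IncrementalResult:
    """Apply a scenario's overrides and evaluate the full pipeline.

    The base parameter set is untouched.  Structural scenarios that require
    user-supplied inputs raise :class:`ScenarioNotRunnable`.
    """
    if not scenario.runnable:
        raise ScenarioNotRunnable(f"scenario {scenario.id} ({scenario.label}) requires user-supplied inputs")
    varied = with_overrides(ps, scenario.overrides) if scenario.overrides else ps.copy_deep()
    res = run_base_case(varied)
    res.scenario_id = scenario.id
    return res


def run_all_scenarios(ps: ParameterSet, scenarios: Sequence[ScenarioSpec] | None = None) -> pd.DataFrame:
    """Summary table over the scenario battery (non-runnable rows marked)."""
    scenarios = scenarios if scenarios is not None else load_scenarios()
    rows = []
    for s in scenarios:
        if not s.runnable:
            rows.append({"id": s.id, "label": s.label, "delta_cost": math.nan, "delta_qaly": math.nan, "icer": "skipped (needs user inputs)", "status": "skipped"})
            continue
        res = run_scenario(ps, s)
        rows.append(
            {
                "id": s.id,
                "label": s.label,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_qaly,
                "icer": res.icer,
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)
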