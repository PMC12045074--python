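"""Model input record: domain types, config I/O and validation.

The complete input to the cost-utility model is a :class:`ParameterSet`
holding the trial arms' procedure costs, 30-day adverse-event probabilities,
monthly Markov transition probabilities, health-state costs, mortality
hazard ratios, utility norms and the general-population life table.

Parameters travel in a versioned YAML document (``schema_version: 1``);
the life table is always a separate CSV with columns
``age,sex,annual_mortality_prob``.  Unknown keys are hard errors — a typo in
a parameter name would otherwise corrupt the ICER invisibly.

All monetary values are SEK at 2022 price level, stored as whole SEK.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Generic, Literal, Optional, TypeVar

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

SCHEMA_VERSION = 1

Arm = Literal["tavi", "savr"]
ARMS: tuple[Arm, Arm] = ("tavi", "savr")
SEXES = ("male", "female")

#: 30-day adverse events captured by the decision tree.
AE_EVENTS = (
    "death",
    "disabling_stroke",
    "non_disabling_stroke",
    "tia",
    "mi",
    "bleeding",
    "aki",
    "new_af",
    "pacemaker",
)

#: Events that allocate the cohort to a day-30 Markov state and are therefore
#: treated as mutually exclusive branches (priority death > stroke > AF).
EXCLUSIVE_AE = ("death", "disabling_stroke", "new_af")

#: Events with one-off costs only; the patient returns to "alive and well".
COSTED_AE = ("non_disabling_stroke", "tia", "mi", "bleeding", "aki")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


T = TypeVar("T")


class PerArm(_Model, Generic[T]):
    """A value specified separately for the TAVI and SAVR arms."""

    tavi: T
    savr: T

    def for_arm(self, arm: Arm) -> T:
        return getattr(self, arm)


class ModelSettings(_Model):
    cycle_length_months: int = 1
    #: ``None`` means lifetime: run to the life table's terminal age.
    horizon_years: Optional[float] = None
    annual_discount_rate_costs: float = 0.03
    annual_discount_rate_outcomes: float = 0.03
    wtp_per_qaly: float = 1_000_000
    start_age_years: float = 75.0
    proportion_male: float = 0.5
    psa_draws: int = 1000
    random_seed: int = 2022
    #: Base case excludes one-off 30-day AE costs; a scenario switches them on.
    include_acute_ae_costs: bool = False
    half_cycle_correction: bool = False


class ProcedureCostInputs(_Model):
    index_procedure_cost: PerArm[int]
    rehab_unit_cost: int
    rehab_rate: PerArm[float]
    pacemaker_unit_cost: int
    pacemaker_rate: PerArm[float]
    #: When set, replaces the rate-based pacemaker component (the published
    #: breakdown prints a component that does not equal unit cost x rate).
    pacemaker_expected_cost_override: PerArm[Optional[int]] = PerArm(
        tavi=None, savr=None
    )


class HealthStateCosts(_Model):
    af_month1: int
    af_month2plus: int
    stroke_month1: int
    stroke_month2plus: int
    caregiver_stroke_month1: int
    caregiver_stroke_month2plus: int
    alive_well_year1_monthly: int
    alive_well_year2plus_monthly: int
    pacemaker_complication_monthly: int
    rehospitalisation_cost: int
    death_cost: int


class ArmEventInputs(_Model):
    """Per-arm event probabilities and one-off adverse-event costs."""

    thirty_day_ae_probs: dict[str, float]
    monthly_aw_to_af: float
    monthly_aw_to_stroke: float
    monthly_af_to_stroke: float
    #: Monthly rehospitalisation probability for years 1, 2 and 3; the year-3
    #: value applies for the remaining horizon.
    monthly_rehosp_by_year: list[float]
    monthly_reintervention: float
    ae_costs: dict[str, int]


class EventProbabilities(_Model):
    tavi: ArmEventInputs
    savr: ArmEventInputs

    def for_arm(self, arm: Arm) -> ArmEventInputs:
        return getattr(self, arm)


class MortalityModifiers(_Model):
    hr_death_af: float
    hr_death_stroke: float
    #: Relative risk of reintervention, applied to the TAVI arm's monthly
    #: reintervention probability.
    rr_reintervention: float = 1.0


class AgeBandNorm(_Model):
    """Population EQ-5D utility norm for ages >= ``age_min``, by sex."""

    age_min: int
    male: float
    female: float


class UtilityInputs(_Model):
    population_norm_by_age_sex: list[AgeBandNorm]
    decrement_af: float
    decrement_stroke: float

    def norm(self, age: float, proportion_male: float) -> float:
        """Sex-weighted population utility norm at ``age`` (band lookup)."""
        bands = sorted(self.population_norm_by_age_sex, key=lambda b: b.age_min)
        chosen = bands[0]
        for b in bands:
            if age >= b.age_min:
                chosen = b
        return proportion_male * chosen.male + (1 - proportion_male) * chosen.female

    def state_utility(self, state: str, age: float, proportion_male: float) -> float:
        """Utility of a living health state: norm minus decrement, floored at 0."""
        u = self.norm(age, proportion_male)
        if state == "treated_af":
            u -= self.decrement_af
        elif state == "disabling_stroke":
            u -= self.decrement_stroke
        return max(u, 0.0)


class LifeTableError(ValueError):
    pass


@dataclass(frozen=True)
class LifeTable:
    """Sex/age-indexed annual all-cause mortality probabilities.

    Ages must be contiguous within each sex and the terminal row of each sex
    must carry probability 1 (everyone dies by the terminal age).
    """

    frame: pd.DataFrame  # columns: age, sex, annual_mortality_prob

    def __post_init__(self) -> None:
        df = self.frame
        required = ["age", "sex", "annual_mortality_prob"]
        if list(df.columns) != required:
            raise LifeTableError(f"life table columns must be {required}, got {list(df.columns)}")
        if df.empty:
            raise LifeTableError("life table is empty")
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise LifeTableError(f"unknown sex values: {sorted(bad_sex)}")
        p = df["annual_mortality_prob"]
        if (p < 0).any() or (p > 1).any():
            raise LifeTableError("annual_mortality_prob outside [0, 1]")
        for sex, grp in df.groupby("sex"):
            ages = grp["age"].to_numpy()
            if len(set(ages)) != len(ages):
                raise LifeTableError(f"duplicate ages for sex={sex}")
            if (ages[1:] - ages[:-1] != 1).any():
                raise LifeTableError(f"gap in age sequence for sex={sex}")
            if grp["annual_mortality_prob"].iloc[-1] != 1.0:
                raise LifeTableError(f"terminal row for sex={sex} must have probability 1")
        object.__setattr__(
            self,
            "_lookup",
            {(int(r.age), r.sex): float(r.annual_mortality_prob) for r in df.itertuples()},
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        df = df.copy()
        df["age"] = df["age"].astype(int)
        df = df.sort_values(["sex", "age"]).reset_index(drop=True)
        return cls(df[["age", "sex", "annual_mortality_prob"]])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df)

    def to_csv(self, path: str | Path) -> None:
        # %.17g keeps the write/read round trip bit-exact
        self.frame.to_csv(path, index=False, float_format="%.17g")

    def sexes(self) -> set[str]:
        return set(self.frame["sex"])

    def min_age(self, sex: str) -> int:
        grp = self.frame[self.frame["sex"] == sex]
        return int(grp["age"].min())

    def terminal_age(self, sex: str) -> int:
        grp = self.frame[self.frame["sex"] == sex]
        return int(grp["age"].max())

    def annual_prob(self, age: int, sex: str) -> float:
        """Annual mortality probability; ages beyond the terminal age return 1."""
        key = (int(age), sex)
        lookup = self._lookup  # type: ignore[attr-defined]
        if key in lookup:
            return lookup[key]
        if age > self.terminal_age(sex):
            return 1.0
        raise LifeTableError(f"age {age} below life-table minimum for sex={sex}")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LifeTable) and self.frame.equals(other.frame)


class ParameterSet(_Model):
    model_config = ConfigDict(extra="forbid", arbitrary_types_allowed=True)

    settings: ModelSettings
    procedure: ProcedureCostInputs
    state_costs: HealthStateCosts
    events: EventProbabilities
    modifiers: MortalityModifiers
    utilities: UtilityInputs
    life_table: LifeTable

    def copy_deep(self) -> "ParameterSet":
        ps = self.model_copy(deep=True)
        # pandas frames are shared by model_copy; the engine never mutates
        # them, but scenario purity is easier to reason about with a real copy
        ps.life_table = LifeTable.from_frame(self.life_table.frame.copy())
        return ps


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field}={self.value!r} violates: {self.rule}"


class ParameterValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        self.violations = violations
        msg = "; ".join(str(v) for v in violations)
        super().__init__(f"invalid parameter set: {msg}")


def _check_fraction(out: list[Violation], field: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        out.append(Violation(field, value, "must lie in [0, 1]"))


def _check_nonneg(out: list[Violation], field: str, value: float) -> None:
    if value < 0:
        out.append(Violation(field, value, "must be >= 0"))


def validate_parameter_set(ps: ParameterSet) -> list[Violation]:
    """Check every model-input invariant; returns violations, never raises."""
    v: list[Violation] = []
    s = ps.settings
    _check_fraction(v, "settings.annual_discount_rate_costs", s.annual_discount_rate_costs)
    _check_fraction(v, "settings.annual_discount_rate_outcomes", s.annual_discount_rate_outcomes)
    _check_fraction(v, "settings.proportion_male", s.proportion_male)
    if s.horizon_years is not None and s.horizon_years <= 0:
        v.append(Violation("settings.horizon_years", s.horizon_years, "must be > 0"))
    if s.psa_draws < 1:
        v.append(Violation("settings.psa_draws", s.psa_draws, "must be >= 1"))
    if s.cycle_length_months != 1:
        v.append(Violation("settings.cycle_length_months", s.cycle_length_months, "must be 1"))
    if s.wtp_per_qaly <= 0:
        v.append(Violation("settings.wtp_per_qaly", s.wtp_per_qaly, "must be > 0"))

    for arm in ARMS:
        _check_nonneg(v, f"procedure.index_procedure_cost.{arm}", ps.procedure.index_procedure_cost.for_arm(arm))
        _check_fraction(v, f"procedure.rehab_rate.{arm}", ps.procedure.rehab_rate.for_arm(arm))
        _check_fraction(v, f"procedure.pacemaker_rate.{arm}", ps.procedure.pacemaker_rate.for_arm(arm))
        override = ps.procedure.pacemaker_expected_cost_override.for_arm(arm)
        if override is not None:
            _check_nonneg(v, f"procedure.pacemaker_expected_cost_override.{arm}", override)
    _check_nonneg(v, "procedure.rehab_unit_cost", ps.procedure.rehab_unit_cost)
    _check_nonneg(v, "procedure.pacemaker_unit_cost", ps.procedure.pacemaker_unit_cost)

    for field, value in ps.state_costs.model_dump().items():
        _check_nonneg(v, f"state_costs.{field}", value)

    for arm in ARMS:
        ev = ps.events.for_arm(arm)
        unknown = set(ev.thirty_day_ae_probs) - set(AE_EVENTS)
        if unknown:
            v.append(Violation(f"events.{arm}.thirty_day_ae_probs", sorted(unknown), "unknown event names"))
        missing = set(AE_EVENTS) - set(ev.thirty_day_ae_probs)
        if missing:
            v.append(Violation(f"events.{arm}.thirty_day_ae_probs", sorted(missing), "missing event names"))
        for name, p in ev.thirty_day_ae_probs.items():
            _check_fraction(v, f"events.{arm}.thirty_day_ae_probs.{name}", p)
        branch_sum = sum(ev.thirty_day_ae_probs.get(e, 0.0) for e in EXCLUSIVE_AE)
        if branch_sum > 1.0 + 1e-12:
            v.append(
                Violation(
                    f"events.{arm}.thirty_day_ae_probs",
                    branch_sum,
                    "mutually exclusive 30-day branch probabilities must sum to <= 1",
                )
            )
        for name in ("monthly_aw_to_af", "monthly_aw_to_stroke", "monthly_af_to_stroke", "monthly_reintervention"):
            _check_fraction(v, f"events.{arm}.{name}", getattr(ev, name))
        if len(ev.monthly_rehosp_by_year) != 3:
            v.append(Violation(f"events.{arm}.monthly_rehosp_by_year", ev.monthly_rehosp_by_year, "must list years 1-3"))
        for i, p in enumerate(ev.monthly_rehosp_by_year):
            _check_fraction(v, f"events.{arm}.monthly_rehosp_by_year[{i}]", p)
        for name, c in ev.ae_costs.items():
            if name not in COSTED_AE:
                v.append(Violation(f"events.{arm}.ae_costs.{name}", c, f"costed events are {COSTED_AE}"))
            _check_nonneg(v, f"events.{arm}.ae_costs.{name}", c)

    for name in ("hr_death_af", "hr_death_stroke", "rr_reintervention"):
        value = getattr(ps.modifiers, name)
        if value <= 0:
            v.append(Violation(f"modifiers.{name}", value, "must be > 0"))

    if not ps.utilities.population_norm_by_age_sex:
        v.append(Violation("utilities.population_norm_by_age_sex", [], "must be non-empty"))
    for band in ps.utilities.population_norm_by_age_sex:
        for sex in SEXES:
            u = getattr(band, sex)
            if not (-1.0 <= u <= 1.0):
                v.append(Violation(f"utilities.population_norm_by_age_sex[{band.age_min}].{sex}", u, "must lie in [-1, 1]"))
    for name in ("decrement_af", "decrement_stroke"):
        _check_nonneg(v, f"utilities.{name}", getattr(ps.utilities, name))

    # life-table / cohort consistency
    start_age = int(math.floor(s.start_age_years))
    needed = []
    if s.proportion_male > 0:
        needed.append("male")
    if s.proportion_male < 1:
        needed.append("female")
    for sex in needed:
        if sex not in ps.life_table.sexes():
            v.append(Violation("life_table", sex, f"missing {sex} rows but cohort has {sex} weight"))
        else:
            if start_age < ps.life_table.min_age(sex):
                v.append(Violation("life_table", start_age, f"start age below {sex} life-table minimum"))
    return v


# ---------------------------------------------------------------------------
# Config file I/O


class ConfigError(ValueError):
    pass


def _parameter_set_to_dict(ps: ParameterSet, life_table_csv: str) -> dict:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "settings": ps.settings.model_dump(),
        "procedure": ps.procedure.model_dump(),
        "state_costs": ps.state_costs.model_dump(),
        "events": ps.events.model_dump(),
        "modifiers": ps.modifiers.model_dump(),
        "utilities": ps.utilities.model_dump(),
        "life_table_csv": life_table_csv,
    }
    return doc


def save_parameter_set(ps: ParameterSet, path: str | Path, life_table_csv: str = "life_table.csv") -> None:
    """Write the YAML document plus the companion life-table CSV."""
    path = Path(path)
    doc = _parameter_set_to_dict(ps, life_table_csv)
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    ps.life_table.to_csv(path.parent / life_table_csv)


def load_parameter_set(path: str | Path, life_table: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file (life table CSV referenced within).

    Raises :class:`ConfigError` for structural problems (missing/unknown keys,
    wrong types) and :class:`ParameterValidationError` when any model
    invariant is violated.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} is not a mapping")
    version = doc.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    lt_ref = doc.pop("life_table_csv", None)
    if life_table is None:
        if lt_ref is None:
            raise ConfigError("missing required field: life_table_csv")
        life_table = path.parent / lt_ref
    lt = LifeTable.from_csv(life_table)

    sections = {"settings", "procedure", "state_costs", "events", "modifiers", "utilities"}
    unknown = set(doc) - sections
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    missing = sections - set(doc)
    if missing:
        raise ConfigError(f"missing required sections: {sorted(missing)}")

    try:
        ps = ParameterSet(
            settings=ModelSettings(**doc["settings"]),
            procedure=ProcedureCostInputs(**doc["procedure"]),
            state_costs=HealthStateCosts(**doc["state_costs"]),
            events=EventProbabilities(**doc["events"]),
            modifiers=MortalityModifiers(**doc["modifiers"]),
            utilities=UtilityInputs(**doc["utilities"]),
            life_table=lt,
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid parameter file {path}: {exc}") from exc

    violations = validate_parameter_set(ps)
    if violations:
        raise ParameterValidationError(violations)
    return ps


def load_life_table(path: str | Path) -> LifeTable:
    """Load a life table CSV (columns ``age,sex,annual_mortality_prob``)."""
    return LifeTable.from_csv(path)


def bundled_base_case_path() -> Path:
    """Path to the packaged base-case parameter file."""
    return Path(__file__).parent / "data" / "base_case.yaml"


def load_base_case() -> ParameterSet:
    """The bundled base-case ParameterSet (printed cost inputs + synthetic
    stand-ins for registry-derived probabilities, utilities and life table)."""
    return load_parameter_set(bundled_base_case_path())
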