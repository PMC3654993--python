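"""Domain types, validation, configuration I/O and the packaged base case.

The model compares antidepressant strategies for major depressive disorder
(MDD) over a monthly-cycle Markov cohort.  Everything the engine consumes is
collected in a :class:`ModelConfig`: per-treatment inputs
(:class:`TreatmentProfile`), disease-level state utilities and costs
(:class:`HealthStateValues`), a background life table with an
episode-mortality multiplier (:class:`MortalitySpec`), relapse survival
specifications (:class:`RelapseSpec`) and economic settings
(:class:`EconomicSettings`).

Configurations round-trip losslessly through YAML (see :func:`load_config` /
:func:`save_config`), and every numeric field is addressable by a dotted
parameter path (``treatments.Venlafaxine.monthly_remission_prob``) so the
sensitivity and probabilistic machinery can vary parameters generically.
"""

from __future__ import annotations

import copy
import enum
import math
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterator

import yaml

__all__ = [
    "AdrName",
    "AdrSpec",
    "RelapseSpec",
    "TreatmentProfile",
    "HealthStateValues",
    "MortalitySpec",
    "EconomicSettings",
    "ModelConfig",
    "ConfigFormatError",
    "ValidationError",
    "ParameterPathError",
    "ValidationWarning",
    "load_config",
    "save_config",
    "load_life_table_csv",
    "paper_base_case",
    "get_param",
    "set_param",
    "with_param",
    "iter_numeric_params",
]


class ConfigFormatError(ValueError):
    """A configuration file could not be parsed or is structurally wrong."""


class ValidationError(ValueError):
    """An invariant on a configuration field is violated.

    The message names the offending field and the bound it breaks.
    """


class ParameterPathError(KeyError):
    """A dotted parameter path does not resolve to a config field."""


class ValidationWarning(UserWarning):
    """Soft invariant violations (e.g. utility ordering under DSA extremes)."""


class AdrName(str, enum.Enum):
    """The eight adverse drug reactions tracked by the model.

    ``sleep_disorder`` is special: sleep problems are attributed to the
    depressive episode itself, so the term is suppressed while the cohort is
    in remission.
    """

    CONSTIPATION = "constipation"
    DYSPEPSIA = "dyspepsia"
    DIARRHOEA = "diarrhoea"
    NAUSEA = "nausea"
    SOMNOLENCE = "somnolence"
    HEADACHE = "headache"
    SEXUAL_DYSFUNCTION = "sexual_dysfunction"
    SLEEP_DISORDER = "sleep_disorder"


def _check_prob(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1]; got {value!r}")


def _check_nonneg(value: float, name: str) -> None:
    if value < 0:
        raise ValidationError(f"{name} must be >= 0; got {value!r}")


def _check_pos(value: float, name: str) -> None:
    if not value > 0:
        raise ValidationError(f"{name} must be > 0; got {value!r}")


@dataclass
class AdrSpec:
    """Utility decrement and monthly management cost of one adverse reaction."""

    name: AdrName
    utility_decrement: float
    monthly_cost: float

    def validate(self) -> None:
        self.name = AdrName(self.name)
        _check_prob(self.utility_decrement, f"adr_table.{self.name.value}.utility_decrement")
        _check_nonneg(self.monthly_cost, f"adr_table.{self.name.value}.monthly_cost")


@dataclass
class RelapseSpec:
    """How monthly relapse risk from remission is generated.

    Either a Weibull relapse-free survival curve (``mode='weibull'``, with
    ``weibull_shape`` dimensionless and ``weibull_scale`` in months) or a
    relative risk applied to a base/placebo Weibull curve
    (``mode='rr_vs_placebo'``).
    """

    mode: str
    weibull_shape: float | None = None
    weibull_scale: float | None = None
    rr: float | None = None

    @classmethod
    def weibull(cls, shape: float, scale: float) -> "RelapseSpec":
        return cls(mode="weibull", weibull_shape=shape, weibull_scale=scale)

    @classmethod
    def rr_vs_placebo(cls, rr: float) -> "RelapseSpec":
        return cls(mode="rr_vs_placebo", rr=rr)

    def validate(self, prefix: str = "relapse") -> None:
        if self.mode == "weibull":
            if self.weibull_shape is None or self.weibull_scale is None:
                raise ValidationError(f"{prefix}: weibull mode requires weibull_shape and weibull_scale")
            if self.rr is not None:
                raise ValidationError(f"{prefix}: weibull mode must not set rr")
            _check_pos(self.weibull_shape, f"{prefix}.weibull_shape")
            _check_pos(self.weibull_scale, f"{prefix}.weibull_scale")
        elif self.mode == "rr_vs_placebo":
            if self.rr is None:
                raise ValidationError(f"{prefix}: rr_vs_placebo mode requires rr")
            if self.weibull_shape is not None or self.weibull_scale is not None:
                raise ValidationError(f"{prefix}: rr_vs_placebo mode must not set weibull parameters")
            _check_pos(self.rr, f"{prefix}.rr")
        else:
            raise ValidationError(f"{prefix}.mode must be 'weibull' or 'rr_vs_placebo'; got {self.mode!r}")


@dataclass
class TreatmentProfile:
    """All drug-specific inputs for one treatment arm."""

    name: str
    daily_dose_mg: float
    double_dose_fraction: float
    monthly_remission_prob: float
    monthly_discontinuation_prob: float
    discontinuation_symptom_prob: float
    relapse: RelapseSpec
    adr_monthly_freq: dict[AdrName, float]
    monthly_drug_cost_standard: float
    hepatic_monitoring: bool = False

    def validate(self) -> None:
        p = f"treatments.{self.name}"
        _check_pos(self.daily_dose_mg, f"{p}.daily_dose_mg")
        _check_prob(self.double_dose_fraction, f"{p}.double_dose_fraction")
        _check_prob(self.monthly_remission_prob, f"{p}.monthly_remission_prob")
        _check_prob(self.monthly_discontinuation_prob, f"{p}.monthly_discontinuation_prob")
        _check_prob(self.discontinuation_symptom_prob, f"{p}.discontinuation_symptom_prob")
        _check_nonneg(self.monthly_drug_cost_standard, f"{p}.monthly_drug_cost_standard")
        self.relapse.validate(prefix=f"{p}.relapse")
        self.adr_monthly_freq = {AdrName(k): v for k, v in self.adr_monthly_freq.items()}
        missing = set(AdrName) - set(self.adr_monthly_freq)
        if missing:
            raise ValidationError(
                f"{p}.adr_monthly_freq missing entries for: " + ", ".join(sorted(m.value for m in missing))
            )
        for adr, freq in self.adr_monthly_freq.items():
            _check_prob(freq, f"{p}.adr_monthly_freq.{adr.value}")


@dataclass
class HealthStateValues:
    """Utilities and monthly state costs (EUR) for the live health states.

    The healthy ("well") state and death carry zero state cost; episode and
    remission each split into direct health-care and indirect (productivity)
    components.
    """

    utility_well: float
    utility_remission: float
    utility_episode: float
    direct_cost_remission: float
    indirect_cost_remission: float
    direct_cost_episode: float
    indirect_cost_episode: float

    def validate(self) -> None:
        for f in ("utility_well", "utility_remission", "utility_episode"):
            _check_prob(getattr(self, f), f"state_values.{f}")
        for f in (
            "direct_cost_remission",
            "indirect_cost_remission",
            "direct_cost_episode",
            "indirect_cost_episode",
        ):
            _check_nonneg(getattr(self, f), f"state_values.{f}")
        if not (self.utility_episode <= self.utility_remission <= self.utility_well):
            warnings.warn(
                "state utilities are not ordered episode <= remission <= well; "
                "allowed (e.g. under sensitivity extremes) but unusual",
                ValidationWarning,
                stacklevel=2,
            )


@dataclass
class MortalitySpec:
    """Background mortality plus the episode (suicide-risk) multiplier.

    ``life_table`` maps integer age in years to the annual probability of
    death; ``episode_mortality_rr`` multiplies the mortality *rate* while the
    cohort is in a depressive episode.
    """

    life_table: dict[int, float]
    episode_mortality_rr: float

    def validate(self) -> None:
        if not self.life_table:
            raise ValidationError("mortality.life_table must not be empty")
        self.life_table = {int(a): float(q) for a, q in self.life_table.items()}
        ages = sorted(self.life_table)
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise ValidationError("mortality.life_table ages must be contiguous integers")
        for a, q in self.life_table.items():
            _check_prob(q, f"mortality.life_table[{a}]")
        if self.episode_mortality_rr < 1:
            raise ValidationError(
                f"mortality.episode_mortality_rr must be >= 1; got {self.episode_mortality_rr!r}"
            )


@dataclass
class EconomicSettings:
    """Analysis settings: discounting, horizon, perspective, thresholds."""

    annual_discount_rate: float = 0.035
    horizon_cycles: int = 24
    start_age_years: float = 45.0
    perspective: str = "societal"
    wtp_thresholds: list[float] = field(default_factory=lambda: [40_000.0, 50_000.0, 60_000.0])
    discontinuation_symptom_duration_days: float = 7.0
    days_per_month: float = 30.0

    def validate(self) -> None:
        if self.horizon_cycles < 1:
            raise ValidationError(f"econ.horizon_cycles must be >= 1; got {self.horizon_cycles!r}")
        _check_nonneg(self.annual_discount_rate, "econ.annual_discount_rate")
        if self.perspective not in ("societal", "payer"):
            raise ValidationError(f"econ.perspective must be 'societal' or 'payer'; got {self.perspective!r}")
        if not self.wtp_thresholds:
            raise ValidationError("econ.wtp_thresholds must not be empty")
        for w in self.wtp_thresholds:
            _check_pos(w, "econ.wtp_thresholds entry")
        _check_pos(self.discontinuation_symptom_duration_days, "econ.discontinuation_symptom_duration_days")
        _check_pos(self.days_per_month, "econ.days_per_month")


@dataclass
class ModelConfig:
    """The complete input set for one model run (all arms)."""

    state_values: HealthStateValues
    mortality: MortalitySpec
    annual_recurrence_prob: float
    adr_table: list[AdrSpec]
    discontinuation_symptom_decrement: float
    discontinuation_symptom_cost: float
    hepatic_test_cost: float
    econ: EconomicSettings
    treatments: list[TreatmentProfile]
    off_treatment_remission_prob: float
    placebo_relapse: RelapseSpec

    def validate(self) -> "ModelConfig":
        self.state_values.validate()
        self.mortality.validate()
        _check_prob(self.annual_recurrence_prob, "annual_recurrence_prob")
        _check_prob(self.off_treatment_remission_prob, "off_treatment_remission_prob")
        _check_prob(self.discontinuation_symptom_decrement, "discontinuation_symptom_decrement")
        _check_nonneg(self.discontinuation_symptom_cost, "discontinuation_symptom_cost")
        _check_nonneg(self.hepatic_test_cost, "hepatic_test_cost")
        self.econ.validate()
        for spec in self.adr_table:
            spec.validate()
        names = [AdrName(s.name) for s in self.adr_table]
        if sorted(n.value for n in names) != sorted(n.value for n in AdrName):
            raise ValidationError("adr_table must contain each of the eight ADRs exactly once")
        self.placebo_relapse.validate(prefix="placebo_relapse")
        if self.placebo_relapse.mode != "weibull":
            raise ValidationError("placebo_relapse must be a weibull spec (it is the base curve)")
        tnames = [t.name for t in self.treatments]
        if len(set(tnames)) != len(tnames):
            raise ValidationError("treatment names must be unique")
        for t in self.treatments:
            t.validate()
        # horizon must stay inside the life table
        max_age = int(math.floor(self.econ.start_age_years + (self.econ.horizon_cycles - 1) / 12.0))
        ages = self.mortality.life_table
        if int(math.floor(self.econ.start_age_years)) not in ages or max_age not in ages:
            raise ValidationError(
                f"mortality.life_table must cover ages {int(self.econ.start_age_years)}..{max_age}"
            )
        return self

    def treatment(self, name: str) -> TreatmentProfile:
        for t in self.treatments:
            if t.name == name:
                return t
        raise ParameterPathError(
            f"unknown treatment {name!r}; valid choices: {[t.name for t in self.treatments]}"
        )

    def adr(self, name: AdrName | str) -> AdrSpec:
        name = AdrName(name)
        for s in self.adr_table:
            if s.name == name:
                return s
        raise ParameterPathError(f"adr_table has no entry {name.value!r}")


# ---------------------------------------------------------------------------
# YAML serialisation


def _relapse_to_dict(spec: RelapseSpec) -> dict:
    if spec.mode == "weibull":
        return {"mode": "weibull", "weibull_shape": spec.weibull_shape, "weibull_scale": spec.weibull_scale}
    return {"mode": "rr_vs_placebo", "rr": spec.rr}


def config_to_dict(config: ModelConfig) -> dict:
    """Plain-python representation used by YAML/JSON serialisation."""
    return {
        "state_values": {f.name: getattr(config.state_values, f.name) for f in fields(HealthStateValues)},
        "mortality": {
            "episode_mortality_rr": config.mortality.episode_mortality_rr,
            "life_table": dict(sorted(config.mortality.life_table.items())),
        },
        "annual_recurrence_prob": config.annual_recurrence_prob,
        "off_treatment_remission_prob": config.off_treatment_remission_prob,
        "placebo_relapse": _relapse_to_dict(config.placebo_relapse),
        "adr_table": [
            {"name": s.name.value, "utility_decrement": s.utility_decrement, "monthly_cost": s.monthly_cost}
            for s in config.adr_table
        ],
        "discontinuation_symptom_decrement": config.discontinuation_symptom_decrement,
        "discontinuation_symptom_cost": config.discontinuation_symptom_cost,
        "hepatic_test_cost": config.hepatic_test_cost,
        "economics": {
            "annual_discount_rate": config.econ.annual_discount_rate,
            "horizon_cycles": config.econ.horizon_cycles,
            "start_age_years": config.econ.start_age_years,
            "perspective": config.econ.perspective,
            "wtp_thresholds": list(config.econ.wtp_thresholds),
            "discontinuation_symptom_duration_days": config.econ.discontinuation_symptom_duration_days,
            "days_per_month": config.econ.days_per_month,
        },
        "treatments": [
            {
                "name": t.name,
                "daily_dose_mg": t.daily_dose_mg,
                "double_dose_fraction": t.double_dose_fraction,
                "monthly_remission_prob": t.monthly_remission_prob,
                "monthly_discontinuation_prob": t.monthly_discontinuation_prob,
                "discontinuation_symptom_prob": t.discontinuation_symptom_prob,
                "relapse": _relapse_to_dict(t.relapse),
                "adr_monthly_freq": {k.value: v for k, v in sorted(t.adr_monthly_freq.items(), key=lambda kv: kv[0].value)},
                "monthly_drug_cost_standard": t.monthly_drug_cost_standard,
                "hepatic_monitoring": t.hepatic_monitoring,
            }
            for t in config.treatments
        ],
    }


def _relapse_from_dict(d: dict, prefix: str) -> RelapseSpec:
    if not isinstance(d, dict) or "mode" not in d:
        raise ConfigFormatError(f"{prefix}: expected a mapping with a 'mode' key")
    return RelapseSpec(
        mode=d["mode"],
        weibull_shape=d.get("weibull_shape"),
        weibull_scale=d.get("weibull_scale"),
        rr=d.get("rr"),
    )


def config_from_dict(data: dict) -> ModelConfig:
    """Build and validate a :class:`ModelConfig` from its plain-dict form."""
    try:
        econ_d = dict(data.get("economics", {}))
        econ = EconomicSettings(**econ_d)
        sv = HealthStateValues(**data["state_values"])
        mort_d = data["mortality"]
        mortality = MortalitySpec(
            life_table={int(k): float(v) for k, v in mort_d["life_table"].items()},
            episode_mortality_rr=float(mort_d["episode_mortality_rr"]),
        )
        adr_table = [
            AdrSpec(name=AdrName(e["name"]), utility_decrement=e["utility_decrement"], monthly_cost=e["monthly_cost"])
            for e in data["adr_table"]
        ]
        treatments = [
            TreatmentProfile(
                name=e["name"],
                daily_dose_mg=e["daily_dose_mg"],
                double_dose_fraction=e["double_dose_fraction"],
                monthly_remission_prob=e["monthly_remission_prob"],
                monthly_discontinuation_prob=e["monthly_discontinuation_prob"],
                discontinuation_symptom_prob=e["discontinuation_symptom_prob"],
                relapse=_relapse_from_dict(e["relapse"], f"treatments.{e.get('name', '?')}.relapse"),
                adr_monthly_freq={AdrName(k): float(v) for k, v in e["adr_monthly_freq"].items()},
                monthly_drug_cost_standard=e["monthly_drug_cost_standard"],
                hepatic_monitoring=bool(e.get("hepatic_monitoring", False)),
            )
            for e in data["treatments"]
        ]
        config = ModelConfig(
            state_values=sv,
            mortality=mortality,
            annual_recurrence_prob=float(data["annual_recurrence_prob"]),
            adr_table=adr_table,
            discontinuation_symptom_decrement=float(data["discontinuation_symptom_decrement"]),
            discontinuation_symptom_cost=float(data["discontinuation_symptom_cost"]),
            hepatic_test_cost=float(data["hepatic_test_cost"]),
            econ=econ,
            treatments=treatments,
            off_treatment_remission_prob=float(data["off_treatment_remission_prob"]),
            placebo_relapse=_relapse_from_dict(data["placebo_relapse"], "placebo_relapse"),
        )
    except ValidationError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigFormatError(f"malformed configuration: {exc}") from exc
    return config.validate()


def load_config(path) -> ModelConfig:
    """Load and validate a model configuration from a YAML file."""
    with open(path, "r") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigFormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigFormatError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def save_config(config: ModelConfig, path) -> None:
    """Write a configuration as YAML (round-trips losslessly with load_config)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_life_table_csv(path) -> dict[int, float]:
    """Read a life table from CSV with header ``age,annual_death_prob``."""
    import csv

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != ["age", "annual_death_prob"]:
            raise ConfigFormatError(f"{path}: expected header 'age,annual_death_prob'")
        return {int(row["age"]): float(row["annual_death_prob"]) for row in reader}


# ---------------------------------------------------------------------------
# Packaged base case
#
# Values marked "published input" below are the published model inputs for the
# Greek 2012 evaluation (drug doses, probabilities, ADR frequencies,
# utilities, costs).  Values marked "package default" stand in for inputs that
# were never published (life table, relapse survival parameters, off-treatment
# remission); their rationale is in docs/methods.md.

_ADR_TABLE = [
    # name, utility decrement, monthly management cost (EUR) — published inputs
    ("constipation", 0.065, 12.5),
    ("dyspepsia", 0.086, 12.0),
    ("diarrhoea", 0.044, 5.5),
    ("nausea", 0.065, 6.0),
    ("somnolence", 0.085, 0.0),  # drowsiness assumed untreated
    ("headache", 0.115, 2.8),
    ("sexual_dysfunction", 0.049, 44.0),
    ("sleep_disorder", 0.08095, 54.0),  # lower of the two published insomnia decrements
]

# ADR monthly frequencies per arm (published inputs), in _ADR_TABLE order.
_ADR_FREQ = {
    "Agomelatine": [0.027, 0.020, 0.040, 0.066, 0.035, 0.111, 0.005, 0.007],
    "Venlafaxine": [0.042, 0.024, 0.018, 0.226, 0.048, 0.119, 0.018, 0.024],
    "Fluoxetine": [0.011, 0.008, 0.027, 0.114, 0.034, 0.114, 0.004, 0.019],
    "Sertraline": [0.006, 0.013, 0.057, 0.044, 0.013, 0.101, 0.019, 0.019],
    "Escitalopram": [0.006, 0.025, 0.069, 0.138, 0.038, 0.144, 0.013, 0.025],
}

# Relapse-free survival on active treatment (agomelatine/venlafaxine share one
# curve): package default Weibull calibrated to 6-month relapse-free survival
# of 0.78 with constant hazard (shape 1).  The placebo curve is calibrated to
# 0.60 at 6 months so that the published relative risks (~0.51-0.63 vs
# placebo) land the SSRI arms near the active curve.
TREATMENT_RELAPSE_SHAPE = 1.0
TREATMENT_RELAPSE_SCALE = 6.0 / -math.log(0.78)  # ~24.149 months
PLACEBO_RELAPSE_SHAPE = 1.0
PLACEBO_RELAPSE_SCALE = 6.0 / -math.log(0.60)  # ~11.746 months

# name, dose mg, double-dose fraction, remission, discontinuation,
# discontinuation-symptom prob, relapse spec, monthly drug cost (EUR),
# hepatic monitoring — published inputs except where noted.
_BRANDED = [
    ("Agomelatine", 25.0, 0.221, 0.323, 0.117, 0.00, ("weibull",), 60.27, True),
    ("Venlafaxine", 75.0, 0.118, 0.323, 0.216, 0.20, ("weibull",), 18.03, False),
    ("Sertraline", 50.0, 0.245, 0.289, 0.189, 0.00, ("rr", 0.633), 17.35, False),
    ("Escitalopram", 20.0, 0.000, 0.323, 0.144, 0.07, ("rr", 0.531), 56.31, False),
    ("Fluoxetine", 20.0, 0.230, 0.284, 0.171, 0.00, ("rr", 0.513), 21.31, False),
]

# Generic arms: price differs, effectiveness and safety copied from branded.
_GENERIC_PRICES = {
    "Venlafaxine": 14.38,
    "Sertraline": 10.81,
    "Escitalopram": 45.60,
    "Fluoxetine": 14.37,
}


def _make_relapse(spec: tuple) -> RelapseSpec:
    if spec[0] == "weibull":
        return RelapseSpec.weibull(TREATMENT_RELAPSE_SHAPE, TREATMENT_RELAPSE_SCALE)
    return RelapseSpec.rr_vs_placebo(spec[1])


def paper_base_case() -> ModelConfig:
    """The packaged base-case configuration: 5 branded + 4 generic arms.

    Published inputs fill every field that the source evaluation printed;
    unprinted inputs (life table, relapse Weibull parameters, off-treatment
    remission) use documented package defaults.
    """
    from .synthetic_data import gompertz_life_table  # deferred: avoids import cycle

    treatments: list[TreatmentProfile] = []
    for name, dose, dd, rem, disc, symp, rel, cost, hep in _BRANDED:
        freqs = {AdrName(adr[0]): f for adr, f in zip(_ADR_TABLE, _ADR_FREQ[name])}
        treatments.append(
            TreatmentProfile(
                name=name,
                daily_dose_mg=dose,
                double_dose_fraction=dd,
                monthly_remission_prob=rem,
                monthly_discontinuation_prob=disc,
                discontinuation_symptom_prob=symp,
                relapse=_make_relapse(rel),
                adr_monthly_freq=freqs,
                monthly_drug_cost_standard=cost,
                hepatic_monitoring=hep,
            )
        )
    for name, dose, dd, rem, disc, symp, rel, _cost, hep in _BRANDED:
        if name not in _GENERIC_PRICES:
            continue
        branded = next(t for t in treatments if t.name == name)
        generic = copy.deepcopy(branded)
        generic.name = f"Generic {name}"
        generic.monthly_drug_cost_standard = _GENERIC_PRICES[name]
        treatments.append(generic)

    config = ModelConfig(
        state_values=HealthStateValues(
            utility_well=0.86,  # published input
            utility_remission=0.81,  # published input
            utility_episode=0.57,  # published input
            direct_cost_remission=35.0,  # published input
            indirect_cost_remission=173.0,  # published input
            direct_cost_episode=190.0,  # published input
            indirect_cost_episode=380.0,  # published input
        ),
        mortality=MortalitySpec(
            # package default: Gompertz stand-in for the unpublished national table
            life_table=gompertz_life_table(a=2e-5, b=0.1, age_min=18, age_max=100),
            episode_mortality_rr=20.35,  # published input (suicide-risk multiplier)
        ),
        annual_recurrence_prob=0.20,  # published input, read as annual
        adr_table=[AdrSpec(AdrName(n), d, c) for n, d, c in _ADR_TABLE],
        discontinuation_symptom_decrement=0.065,  # published input (= nausea decrement)
        discontinuation_symptom_cost=52.0,  # published input
        hepatic_test_cost=75.0,  # published input
        econ=EconomicSettings(),
        treatments=treatments,
        off_treatment_remission_prob=0.20,  # package default: untreated monthly remission
        placebo_relapse=RelapseSpec.weibull(PLACEBO_RELAPSE_SHAPE, PLACEBO_RELAPSE_SCALE),
    )
    return config.validate()


# ---------------------------------------------------------------------------
# Dotted parameter paths


def _step(obj, part: str, path: str):
    if isinstance(obj, dict):
        for key in obj:
            if (key.value if isinstance(key, AdrName) else str(key)) == part:
                return obj[key]
        raise ParameterPathError(f"{path}: no key {part!r}")
    if isinstance(obj, list):
        for item in obj:
            name = getattr(item, "name", None)
            if (name.value if isinstance(name, AdrName) else name) == part:
                return item
        raise ParameterPathError(f"{path}: no element named {part!r}")
    if part == "economics":  # external alias for the econ settings block
        part = "econ"
    if not hasattr(obj, part):
        raise ParameterPathError(f"{path}: {type(obj).__name__} has no field {part!r}")
    return getattr(obj, part)


def get_param(config: ModelConfig, path: str) -> float:
    """Resolve a dotted parameter path to its current value."""
    obj = config
    for part in path.split("."):
        obj = _step(obj, part, path)
    return obj


def set_param(config: ModelConfig, path: str, value) -> None:
    """Set a dotted parameter path in place (no validation; see with_param)."""
    parts = path.split(".")
    obj = config
    for part in parts[:-1]:
        obj = _step(obj, part, path)
    last = parts[-1]
    if isinstance(obj, dict):
        for key in obj:
            if (key.value if isinstance(key, AdrName) else str(key)) == last:
                obj[key] = value
                return
        raise ParameterPathError(f"{path}: no key {last!r}")
    if last == "economics":
        last = "econ"
    if not hasattr(obj, last):
        raise ParameterPathError(f"{path}: {type(obj).__name__} has no field {last!r}")
    setattr(obj, last, value)


def with_param(config: ModelConfig, path: str, value, validate: bool = True) -> ModelConfig:
    """Return a deep copy of ``config`` with one parameter replaced."""
    new = copy.deepcopy(config)
    set_param(new, path, value)
    if validate:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ValidationWarning)
            new.validate()
    return new


def iter_numeric_params(config: ModelConfig) -> Iterator[tuple[str, float, str]]:
    """Yield ``(path, value, kind)`` for every scalar model parameter.

    ``kind`` classifies the parameter for distribution assignment and
    sensitivity ranges: ``probability``, ``utility``, ``cost``, ``rr`` or
    ``positive`` (positive-scale quantities such as Weibull parameters).
    Structural settings (horizon, discount rate, ages, life table rows) are
    not enumerated; they remain addressable by explicit path.
    """
    sv = config.state_values
    for f in ("utility_well", "utility_remission", "utility_episode"):
        yield f"state_values.{f}", getattr(sv, f), "utility"
    for f in ("direct_cost_remission", "indirect_cost_remission", "direct_cost_episode", "indirect_cost_episode"):
        yield f"state_values.{f}", getattr(sv, f), "cost"
    yield "annual_recurrence_prob", config.annual_recurrence_prob, "probability"
    yield "off_treatment_remission_prob", config.off_treatment_remission_prob, "probability"
    yield "discontinuation_symptom_decrement", config.discontinuation_symptom_decrement, "utility"
    yield "discontinuation_symptom_cost", config.discontinuation_symptom_cost, "cost"
    yield "hepatic_test_cost", config.hepatic_test_cost, "cost"
    yield "mortality.episode_mortality_rr", config.mortality.episode_mortality_rr, "rr"
    for spec in config.adr_table:
        yield f"adr_table.{spec.name.value}.utility_decrement", spec.utility_decrement, "utility"
        yield f"adr_table.{spec.name.value}.monthly_cost", spec.monthly_cost, "cost"
    yield "placebo_relapse.weibull_shape", config.placebo_relapse.weibull_shape, "positive"
    yield "placebo_relapse.weibull_scale", config.placebo_relapse.weibull_scale, "positive"
    for t in config.treatments:
        p = f"treatments.{t.name}"
        yield f"{p}.double_dose_fraction", t.double_dose_fraction, "probability"
        yield f"{p}.monthly_remission_prob", t.monthly_remission_prob, "probability"
        yield f"{p}.monthly_discontinuation_prob", t.monthly_discontinuation_prob, "probability"
        yield f"{p}.discontinuation_symptom_prob", t.discontinuation_symptom_prob, "probability"
        yield f"{p}.monthly_drug_cost_standard", t.monthly_drug_cost_standard, "cost"
        if t.relapse.mode == "rr_vs_placebo":
            yield f"{p}.relapse.rr", t.relapse.rr, "rr"
        else:
            yield f"{p}.relapse.weibull_shape", t.relapse.weibull_shape, "positive"
            yield f"{p}.relapse.weibull_scale", t.relapse.weibull_scale, "positive"
        for adr in AdrName:
            yield f"{p}.adr_monthly_freq.{adr.value}", t.adr_monthly_freq[adr], "probability"
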