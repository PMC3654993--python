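"""Generators for inputs the published evaluation left unprinted.

Three kinds of stand-in data make the whole pipeline testable end to end:

* a Gompertz-hazard life table emulating an adult all-cause mortality table,
* Weibull relapse-free survival points (exact closed form) for curve fitting,
* fully randomised but structurally valid model configurations.

All randomness is driven by an explicit seed; the same seed always produces
the same output.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    AdrName,
    ModelConfig,
    RelapseSpec,
    TreatmentProfile,
    ValidationError,
    paper_base_case,
)

__all__ = [
    "SurvivalPoint",
    "ScenarioSeed",
    "gompertz_life_table",
    "weibull_survival_points",
    "random_scenario",
    "write_life_table_csv",
    "write_survival_points_csv",
]


@dataclass(frozen=True)
class SurvivalPoint:
    """One (time, survival) observation on a relapse-free survival curve."""

    time: float  # months
    survival: float  # probability, in (0, 1]


def gompertz_life_table(a: float, b: float, age_min: int, age_max: int) -> dict[int, float]:
    """Annual death probabilities from a Gompertz hazard h(x) = a·exp(b·x).

    The annual probability at integer age x is the cumulative hazard over
    [x, x+1]::

        q(x) = 1 - exp(-(a/b)·(e^{b(x+1)} - e^{bx}))      for b > 0
        q(x) = 1 - exp(-a)                                 for b = 0

    Parameters are per-year; the default adult calibration used by the
    packaged base case is a=2e-5, b=0.1.
    """
    if not a > 0:
        raise ValidationError(f"gompertz baseline hazard a must be > 0; got {a!r}")
    if b < 0:
        raise ValidationError(f"gompertz slope b must be >= 0; got {b!r}")
    if not age_min < age_max:
        raise ValidationError("age_min must be < age_max")
    table: dict[int, float] = {}
    for age in range(age_min, age_max + 1):
        if b == 0:
            cum = a
        else:
            cum = (a / b) * (math.exp(b * (age + 1)) - math.exp(b * age))
        table[age] = 1.0 - math.exp(-cum)
    return table


def weibull_survival_points(shape: float, scale: float, times) -> list[SurvivalPoint]:
    """Exact Weibull relapse-free survival S(t) = exp(-(t/scale)^shape)."""
    if not shape > 0:
        raise ValidationError(f"weibull shape must be > 0; got {shape!r}")
    if not scale > 0:
        raise ValidationError(f"weibull scale must be > 0; got {scale!r}")
    times = list(times)
    if any(t < 0 for t in times):
        raise ValidationError("times must be >= 0")
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValidationError("times must be strictly increasing")
    return [SurvivalPoint(time=t, survival=math.exp(-((t / scale) ** shape))) for t in times]


# Default sampling ranges for random scenarios.  Probabilities stay moderate
# so random configs remain epidemiologically plausible (monthly event risks
# well below 1); costs span the order of magnitude of the base-case values.
_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "utility_well": (0.80, 0.95),
    "utility_remission": (0.65, 0.85),
    "utility_episode": (0.40, 0.65),
    "direct_cost_remission": (10.0, 80.0),
    "indirect_cost_remission": (50.0, 300.0),
    "direct_cost_episode": (100.0, 400.0),
    "indirect_cost_episode": (150.0, 600.0),
    "annual_recurrence_prob": (0.05, 0.40),
    "off_treatment_remission_prob": (0.05, 0.35),
    "episode_mortality_rr": (1.0, 30.0),
    "monthly_remission_prob": (0.10, 0.45),
    "monthly_discontinuation_prob": (0.02, 0.30),
    "discontinuation_symptom_prob": (0.0, 0.30),
    "double_dose_fraction": (0.0, 0.35),
    "adr_freq": (0.0, 0.15),
    "adr_decrement": (0.01, 0.15),
    "adr_cost": (0.0, 60.0),
    "drug_cost": (5.0, 80.0),
    "rr": (0.3, 1.0),
    "weibull_shape": (0.6, 1.6),
    "weibull_scale": (6.0, 36.0),
    "gompertz_a": (5e-6, 1e-4),
    "gompertz_b": (0.05, 0.12),
}


@dataclass
class ScenarioSeed:
    """Reproducible recipe for one randomised configuration."""

    rng_seed: int
    n_treatments: int = 3
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def merged_ranges(self) -> dict[str, tuple[float, float]]:
        out = dict(_DEFAULT_RANGES)
        out.update(self.ranges)
        for key, (lo, hi) in out.items():
            if lo > hi:
                raise ValidationError(f"range for {key!r} has low > high")
        return out


def random_scenario(seed: ScenarioSeed) -> ModelConfig:
    """Draw a structurally valid random configuration.

    Starts from the packaged base case (so structural settings such as the
    horizon and the ADR catalogue are sensible) and redraws every varied
    scalar uniformly within the scenario ranges.  Utilities are drawn in the
    order well >= remission >= episode by rejection-free clamping of the
    range tops, so the ordering invariant always holds.
    """
    if seed.n_treatments < 1:
        raise ValidationError("n_treatments must be >= 1")
    rng = np.random.default_rng(seed.rng_seed)
    r = seed.merged_ranges()

    def u(key: str) -> float:
        lo, hi = r[key]
        return float(rng.uniform(lo, hi))

    config = paper_base_case()
    sv = config.state_values
    sv.utility_well = u("utility_well")
    sv.utility_remission = min(u("utility_remission"), sv.utility_well)
    sv.utility_episode = min(u("utility_episode"), sv.utility_remission)
    sv.direct_cost_remission = u("direct_cost_remission")
    sv.indirect_cost_remission = u("indirect_cost_remission")
    sv.direct_cost_episode = u("direct_cost_episode")
    sv.indirect_cost_episode = u("indirect_cost_episode")
    config.annual_recurrence_prob = u("annual_recurrence_prob")
    config.off_treatment_remission_prob = u("off_treatment_remission_prob")
    config.mortality.episode_mortality_rr = max(1.0, u("episode_mortality_rr"))
    config.mortality.life_table = gompertz_life_table(
        a=u("gompertz_a"), b=u("gompertz_b"), age_min=18, age_max=100
    )
    for spec in config.adr_table:
        spec.utility_decrement = u("adr_decrement")
        spec.monthly_cost = u("adr_cost")
    config.placebo_relapse = RelapseSpec.weibull(u("weibull_shape"), u("weibull_scale"))

    base_adrs = list(AdrName)
    treatments: list[TreatmentProfile] = []
    for i in range(seed.n_treatments):
        mode = rng.integers(0, 2)
        relapse = (
            RelapseSpec.weibull(u("weibull_shape"), u("weibull_scale"))
            if mode == 0
            else RelapseSpec.rr_vs_placebo(u("rr"))
        )
        treatments.append(
            TreatmentProfile(
                name=f"Drug{i + 1}",
                daily_dose_mg=float(rng.uniform(10, 100)),
                double_dose_fraction=u("double_dose_fraction"),
                monthly_remission_prob=u("monthly_remission_prob"),
                monthly_discontinuation_prob=u("monthly_discontinuation_prob"),
                discontinuation_symptom_prob=u("discontinuation_symptom_prob"),
                relapse=relapse,
                adr_monthly_freq={adr: u("adr_freq") for adr in base_adrs},
                monthly_drug_cost_standard=u("drug_cost"),
                hepatic_monitoring=bool(rng.integers(0, 2)),
            )
        )
    config.treatments = treatments
    return config.validate()


def write_life_table_csv(table: dict[int, float], path) -> None:
    """Write a life table as CSV with header ``age,annual_death_prob``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age", "annual_death_prob"])
        for age in sorted(table):
            writer.writerow([age, repr(table[age])])


def write_survival_points_csv(points: list[SurvivalPoint], path) -> None:
    """Write survival points as CSV with header ``time_months,survival``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_months", "survival"])
        for p in points:
            writer.writerow([repr(p.time), repr(p.survival)])
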