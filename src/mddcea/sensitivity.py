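"""Deterministic sensitivity analysis, named scenarios and break-even search.

One-way DSA re-runs a pairwise comparison at the low and high extreme of each
parameter and ranks parameters by the width of the resulting net-monetary-
benefit span (tornado order).  Named scenarios apply structural transforms
(payer perspective, exclusion of adverse events / sleep disorder /
discontinuation, a 12-month horizon, or an arbitrary single-parameter
change).  The break-even search bisects a comparator's monthly remission
probability for the point where the reference arm becomes dominated.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .economics import CEResult, incremental_analysis, summarize_arm
from .markov_engine import run_cohort
from .parameters import (
    AdrName,
    ModelConfig,
    ValidationError,
    get_param,
    iter_numeric_params,
    with_param,
)

__all__ = [
    "DsaEntry",
    "Scenario",
    "run_pair",
    "run_dsa",
    "default_param_grid",
    "run_scenario",
    "apply_scenario",
    "breakeven_remission",
    "DEFAULT_REFERENCE_THRESHOLD",
]

DEFAULT_REFERENCE_THRESHOLD = 50_000.0


def run_pair(config: ModelConfig, treatment: str, comparator: str) -> CEResult:
    """Base-case pairwise comparison of two named arms under one config."""
    t = config.treatment(treatment)
    c = config.treatment(comparator)
    res_t = summarize_arm(run_cohort(t, config), t, config)
    res_c = summarize_arm(run_cohort(c, config), c, config)
    return incremental_analysis(res_t, res_c, config.econ.wtp_thresholds)


@dataclass
class DsaEntry:
    """One tornado row: a parameter varied to its extremes."""

    path: str
    low: float
    high: float
    result_low: CEResult
    result_high: CEResult
    nmb_low: float
    nmb_high: float

    @property
    def span(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def default_param_grid(
    config: ModelConfig, fraction: float = 0.20
) -> list[tuple[str, float, float]]:
    """Symmetric +/- ``fraction`` extremes for every scalar parameter.

    Extremes are clamped to the parameter's type bounds (probabilities and
    utilities to [0, 1]).  Zero-valued parameters yield a degenerate range.
    """
    grid = []
    for path, value, kind in iter_numeric_params(config):
        lo = value * (1.0 - fraction)
        hi = value * (1.0 + fraction)
        if kind in ("probability", "utility"):
            hi = min(hi, 1.0)
        grid.append((path, lo, hi))
    return grid


def run_dsa(
    config: ModelConfig,
    arm_pair: tuple[str, str],
    param_grid: list[tuple[str, float, float]] | None = None,
    reference_threshold: float = DEFAULT_REFERENCE_THRESHOLD,
) -> list[DsaEntry]:
    """One-way DSA over ``param_grid``, sorted by |NMB span| descending."""
    if param_grid is None:
        param_grid = default_param_grid(config)
    treatment, comparator = arm_pair
    entries = []
    for path, lo, hi in param_grid:
        if lo > hi:
            raise ValidationError(f"DSA extreme for {path}: low {lo} > high {hi}")
        get_param(config, path)  # raises ParameterPathError on bad paths
        res_lo = run_pair(with_param(config, path, lo), treatment, comparator)
        res_hi = run_pair(with_param(config, path, hi), treatment, comparator)
        nmb_lo = reference_threshold * res_lo.incremental_qalys - res_lo.incremental_cost
        nmb_hi = reference_threshold * res_hi.incremental_qalys - res_hi.incremental_cost
        entries.append(DsaEntry(path, lo, hi, res_lo, res_hi, nmb_lo, nmb_hi))
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


_SCENARIO_KINDS = (
    "payer_perspective",
    "exclude_adr",
    "exclude_sleep",
    "exclude_discontinuation",
    "horizon_12",
    "vary",
)


@dataclass
class Scenario:
    """A named structural transform of the configuration."""

    name: str
    kind: str
    vary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _SCENARIO_KINDS:
            raise ValidationError(
                f"unknown scenario kind {self.kind!r}; valid: {', '.join(_SCENARIO_KINDS)}"
            )


def apply_scenario(config: ModelConfig, scenario: Scenario) -> ModelConfig:
    """Return the transformed (and re-validated) configuration."""
    new = copy.deepcopy(config)
    if scenario.kind == "payer_perspective":
        new.econ.perspective = "payer"
    elif scenario.kind == "exclude_adr":
        for t in new.treatments:
            t.adr_monthly_freq = {adr: 0.0 for adr in AdrName}
    elif scenario.kind == "exclude_sleep":
        for t in new.treatments:
            t.adr_monthly_freq[AdrName.SLEEP_DISORDER] = 0.0
    elif scenario.kind == "exclude_discontinuation":
        for t in new.treatments:
            t.monthly_discontinuation_prob = 0.0
    elif scenario.kind == "horizon_12":
        new.econ.horizon_cycles = 12
    elif scenario.kind == "vary":
        for path, value in scenario.vary.items():
            from .parameters import set_param

            set_param(new, path, value)
    return new.validate()


def run_scenario(config: ModelConfig, scenario: Scenario, arm_pair: tuple[str, str]) -> CEResult:
    """Pairwise comparison under a transformed configuration."""
    return run_pair(apply_scenario(config, scenario), *arm_pair)


def breakeven_remission(
    config: ModelConfig,
    comparator: str,
    tolerance: float = 1e-4,
    reference: str | None = None,
) -> float:
    """Smallest comparator remission probability that dominates the reference.

    Bisects the comparator's monthly remission probability on
    ``[base, 1.0]`` for the lowest value at which the reference arm (by
    default the first treatment) is dominated (dQ <= 0 and dC >= 0).
    Returns 1.0 as a sentinel when no crossing exists in the bracket.
    """
    ref_name = reference if reference is not None else config.treatments[0].name
    comp = config.treatment(comparator)  # raises on unknown names
    if comp.name == ref_name:
        raise ValidationError("comparator must differ from the reference arm")
    path = f"treatments.{comparator}.monthly_remission_prob"
    base = get_param(config, path)

    def dominated(r: float) -> bool:
        res = run_pair(with_param(config, path, r), ref_name, comparator)
        return res.incremental_qalys <= 0 and res.incremental_cost >= 0

    if dominated(base):
        raise ValidationError(
            f"{ref_name} is already dominated by {comparator} at the base remission rate"
        )
    if not dominated(1.0):
        return 1.0  # sentinel: no crossing in the bracket
    lo, hi = base, 1.0  # invariant: not dominated(lo), dominated(hi)
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if dominated(mid):
            hi = mid
        else:
            lo = mid
    return hi
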