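"""Costing, discounting, per-arm totals and incremental cost-utility analysis.

Health outcomes are quality-adjusted life years (QALYs): each monthly cycle
contributes state utility / 12, net of expected adverse-reaction disutility.
Costs split into drug, direct medical, indirect (productivity), adverse-event
management and hepatic-monitoring components.  Discounting starts after the
first model year.  Pairwise comparisons report incremental cost, incremental
QALYs, the ICER or a dominance label, and net monetary benefit (NMB) at the
configured willingness-to-pay thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .parameters import AdrName, AdrSpec, ModelConfig, TreatmentProfile, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .markov_engine import CohortTrace

__all__ = [
    "ArmResult",
    "CEResult",
    "expected_adr_disutility",
    "expected_adr_cost",
    "medication_cost",
    "discount_factor",
    "summarize_arm",
    "incremental_analysis",
    "DOMINANT",
    "DOMINATED",
]

DOMINANT = "dominant"
DOMINATED = "dominated"


def _adr_map(adr_table: list[AdrSpec]) -> dict[AdrName, AdrSpec]:
    return {AdrName(s.name): s for s in adr_table}


def expected_adr_disutility(
    profile: TreatmentProfile, adr_table: list[AdrSpec], include_sleep: bool
) -> float:
    """Expected per-cycle utility decrease from adverse drug reactions.

    Sum over reactions of monthly frequency x utility decrement.  Sleep
    disorder is attributed to the depressive episode itself and therefore
    only counted when ``include_sleep`` is true (episode states).
    """
    table = _adr_map(adr_table)
    total = 0.0
    for adr in AdrName:
        if adr is AdrName.SLEEP_DISORDER and not include_sleep:
            continue
        if adr not in profile.adr_monthly_freq:
            raise ValidationError(f"{profile.name}: missing ADR frequency for {adr.value}")
        total += profile.adr_monthly_freq[adr] * table[adr].utility_decrement
    return total


def expected_adr_cost(
    profile: TreatmentProfile, adr_table: list[AdrSpec], include_sleep: bool
) -> float:
    """Expected per-cycle ADR management cost (EUR), same sleep rule."""
    table = _adr_map(adr_table)
    total = 0.0
    for adr in AdrName:
        if adr is AdrName.SLEEP_DISORDER and not include_sleep:
            continue
        if adr not in profile.adr_monthly_freq:
            raise ValidationError(f"{profile.name}: missing ADR frequency for {adr.value}")
        total += profile.adr_monthly_freq[adr] * table[adr].monthly_cost
    return total


def medication_cost(profile: TreatmentProfile, cycle_on_treatment: int) -> float:
    """Monthly drug cost, with dose escalation from the second cycle on.

    From cycle 2 onward the expected cost is inflated by the fraction of
    patients titrated to double dose.
    """
    if cycle_on_treatment < 1:
        raise ValidationError(f"cycle_on_treatment must be >= 1; got {cycle_on_treatment!r}")
    if cycle_on_treatment == 1:
        return profile.monthly_drug_cost_standard
    return profile.monthly_drug_cost_standard * (1.0 + profile.double_dose_fraction)


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Discount factor for a monthly cycle; the first year is undiscounted."""
    if cycle < 1:
        raise ValidationError(f"cycle must be >= 1; got {cycle!r}")
    if cycle <= 12:
        return 1.0
    return float((1.0 + annual_rate) ** (-(cycle - 12) / 12.0))


@dataclass
class ArmResult:
    """Discounted totals for one treatment arm."""

    treatment: str
    total_cost: float
    cost_drug: float
    cost_direct_medical: float
    cost_indirect: float
    cost_adr: float
    cost_monitoring: float
    total_qalys: float

    def components(self) -> dict[str, float]:
        return {
            "drug": self.cost_drug,
            "direct_medical": self.cost_direct_medical,
            "indirect": self.cost_indirect,
            "adr": self.cost_adr,
            "monitoring": self.cost_monitoring,
        }


def summarize_arm(trace: "CohortTrace", profile: TreatmentProfile, config: ModelConfig) -> ArmResult:
    """Discount and sum the per-cycle accrual streams of one cohort run.

    Under the payer perspective the indirect (productivity) stream is
    excluded: its component is reported as zero and it does not enter the
    total.
    """
    horizon = config.econ.horizon_cycles
    if len(trace.qaly_stream) != horizon + 1:
        raise ValidationError(
            f"trace horizon {len(trace.qaly_stream) - 1} does not match config horizon {horizon}"
        )
    rate = config.econ.annual_discount_rate
    df = np.array([discount_factor(c, rate) for c in range(1, horizon + 1)])

    def total(stream: np.ndarray) -> float:
        return float(np.dot(df, stream[1:]))

    qalys = total(trace.qaly_stream)
    drug = total(trace.drug_cost_stream)
    direct = total(trace.direct_cost_stream)
    adr = total(trace.adr_cost_stream)
    monitoring = total(trace.monitoring_cost_stream)
    indirect = total(trace.indirect_cost_stream) if config.econ.perspective == "societal" else 0.0
    return ArmResult(
        treatment=profile.name,
        total_cost=drug + direct + indirect + adr + monitoring,
        cost_drug=drug,
        cost_direct_medical=direct,
        cost_indirect=indirect,
        cost_adr=adr,
        cost_monitoring=monitoring,
        total_qalys=qalys,
    )


@dataclass
class CEResult:
    """Pairwise incremental economics of ``treatment`` versus ``comparator``."""

    treatment: str
    comparator: str
    incremental_cost: float
    incremental_qalys: float
    icer: float | None
    label: str  # 'dominant' | 'dominated' | 'icer' | 'undefined'
    nmb_by_threshold: dict[float, float] = field(default_factory=dict)

    def icer_display(self) -> str:
        if self.label in (DOMINANT, DOMINATED):
            return self.label
        if self.icer is None:
            return "undefined"
        return f"{self.icer:.0f}/QALY"


def incremental_analysis(a: ArmResult, b: ArmResult, thresholds: list[float]) -> CEResult:
    """Incremental cost-utility of arm ``a`` relative to arm ``b``.

    Sign convention: increments are a minus b.  ``a`` dominates when it is
    cheaper and more effective; it is dominated when costlier and less
    effective.  A ratio is only reported when both increments share a sign
    (northeast quadrant: cost per QALY gained; southwest: savings per QALY
    forgone, a comparator-favouring ratio).  NMB(lambda) = lambda·dQ - dC.
    """
    d_cost = a.total_cost - b.total_cost
    d_q = a.total_qalys - b.total_qalys
    nmb = {float(w): float(w * d_q - d_cost) for w in thresholds}
    if d_cost < 0 and d_q > 0:
        return CEResult(a.treatment, b.treatment, d_cost, d_q, None, DOMINANT, nmb)
    if d_cost > 0 and d_q < 0:
        return CEResult(a.treatment, b.treatment, d_cost, d_q, None, DOMINATED, nmb)
    if d_q == 0:
        return CEResult(a.treatment, b.treatment, d_cost, d_q, None, "undefined", nmb)
    return CEResult(a.treatment, b.treatment, d_cost, d_q, d_cost / d_q, "icer", nmb)
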