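"""Monthly-cycle Markov cohort engine over the expanded 16-state space.

The clinical model has six health states — depressive episode and remission,
each on and off the original treatment, plus well (recovered) and dead.  A
six-month stay in remission is required before recovery, which a memoryless
chain cannot express directly, so each remission state is expanded into six
one-month tunnel states.  The expanded ordered state space is::

    0            episode_on_tx
    1..6         remission_on_tx_m   (tunnel month m = 1..6)
    7            episode_off_tx
    8..13        remission_off_tx_m  (tunnel month m = 1..6)
    14           well
    15           dead

Event composition within a cycle: death is resolved first (background
mortality from the life table, rate-scale multiplied by the suicide-risk
factor in the two episode states); the surviving mass then splits over the
clinical events using the marginal monthly probabilities (see the
``*_BOTH_EVENTS`` constants for the simultaneous-event tie-breaks).  Relapse
and recurrence always return the cohort to the episode-on-treatment state:
patients resume their original drug.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import expected_adr_cost, expected_adr_disutility, medication_cost
from .parameters import ModelConfig, TreatmentProfile, ValidationError
from .survival import annual_to_monthly_prob, apply_rr_to_prob, monthly_relapse_prob

__all__ = [
    "N_STATES",
    "STATE_NAMES",
    "EP_ON",
    "EP_OFF",
    "WELL",
    "DEAD",
    "REM_ON",
    "REM_OFF",
    "ON_TX_STATES",
    "OFF_TX_STATES",
    "CohortTrace",
    "build_transition_matrix",
    "run_cohort",
    "compute_cycle_accruals",
    "trace_to_frame",
]

TUNNEL_MONTHS = 6

EP_ON = 0
REM_ON = tuple(range(1, 1 + TUNNEL_MONTHS))  # REM_ON[m-1] is tunnel month m
EP_OFF = 7
REM_OFF = tuple(range(8, 8 + TUNNEL_MONTHS))
WELL = 14
DEAD = 15
N_STATES = 16

STATE_NAMES = (
    ["episode_on_tx"]
    + [f"remission_on_tx_{m}" for m in range(1, TUNNEL_MONTHS + 1)]
    + ["episode_off_tx"]
    + [f"remission_off_tx_{m}" for m in range(1, TUNNEL_MONTHS + 1)]
    + ["well", "dead"]
)

ON_TX_STATES = (EP_ON,) + REM_ON
OFF_TX_STATES = (EP_OFF,) + REM_OFF

# Tie-breaks for two clinical events landing in the same cycle (the model's
# inputs are marginal monthly probabilities, so the joint mass must be routed
# explicitly).  From an episode, remit-and-discontinue goes to the first
# off-treatment remission tunnel month (remit, then stop the drug).  From
# remission, relapse-and-discontinue relapses back onto the original
# treatment (relapse trumps discontinuation).
EPISODE_BOTH_EVENTS_STATE = REM_OFF[0]
REMISSION_BOTH_EVENTS_STATE = EP_ON

# Hepatic safety monitoring (blood tests at weeks 3, 6, 12, 24) maps to model
# cycles 1, 2, 3 and 6 on treatment; it is not re-billed after a relapse.
HEPATIC_MONITORING_CYCLES = (1, 2, 3, 6)

_ROW_SUM_TOL = 1e-9


def _background_monthly_death(config: ModelConfig, age: float) -> float:
    age_key = int(math.floor(age))
    try:
        q_annual = config.mortality.life_table[age_key]
    except KeyError:
        raise ValidationError(f"life table does not cover age {age_key}") from None
    return annual_to_monthly_prob(q_annual)


def build_transition_matrix(
    profile: TreatmentProfile, config: ModelConfig, cycle: int, age: float
) -> np.ndarray:
    """Row-stochastic 16x16 one-cycle transition matrix.

    ``cycle`` is the zero-based index of the transition (occupancy at
    ``cycle`` maps to occupancy at ``cycle + 1``); ``age`` is the cohort age
    in years at the start of the cycle.
    """
    if not (0 <= cycle < config.econ.horizon_cycles):
        raise ValidationError(f"cycle {cycle} outside horizon [0, {config.econ.horizon_cycles})")
    q = _background_monthly_death(config, age)
    q_ep = apply_rr_to_prob(q, config.mortality.episode_mortality_rr)

    M = np.zeros((N_STATES, N_STATES))

    # Episode on treatment: remission vs discontinuation among survivors.
    p_rem = profile.monthly_remission_prob
    p_disc = profile.monthly_discontinuation_prob
    s = 1.0 - q_ep
    M[EP_ON, DEAD] = q_ep
    M[EP_ON, REM_ON[0]] = s * p_rem * (1.0 - p_disc)
    M[EP_ON, EP_OFF] = s * p_disc * (1.0 - p_rem)
    M[EP_ON, EPISODE_BOTH_EVENTS_STATE] += s * p_rem * p_disc
    M[EP_ON, EP_ON] = s * (1.0 - p_rem) * (1.0 - p_disc)

    # Remission on treatment (tunnel months): relapse vs discontinuation.
    for m in range(1, TUNNEL_MONTHS + 1):
        i = REM_ON[m - 1]
        p_rel = monthly_relapse_prob(m - 1, profile.relapse, base=config.placebo_relapse)
        s = 1.0 - q
        M[i, DEAD] = q
        # relapse wins the both-events mass, so relapse flow is simply p_rel
        M[i, REMISSION_BOTH_EVENTS_STATE] += s * p_rel * p_disc
        M[i, EP_ON] += s * p_rel * (1.0 - p_disc)
        M[i, REM_OFF[m - 1]] += s * p_disc * (1.0 - p_rel)
        nxt = REM_ON[m] if m < TUNNEL_MONTHS else WELL
        M[i, nxt] += s * (1.0 - p_rel) * (1.0 - p_disc)

    # Episode off treatment: spontaneous remission only, no discontinuation.
    p_rem_off = config.off_treatment_remission_prob
    s = 1.0 - q_ep
    M[EP_OFF, DEAD] = q_ep
    M[EP_OFF, REM_OFF[0]] = s * p_rem_off
    M[EP_OFF, EP_OFF] = s * (1.0 - p_rem_off)

    # Remission off treatment: relapse follows the base (placebo) curve and
    # returns the patient to the original treatment.
    for m in range(1, TUNNEL_MONTHS + 1):
        i = REM_OFF[m - 1]
        p_rel = monthly_relapse_prob(m - 1, config.placebo_relapse)
        s = 1.0 - q
        M[i, DEAD] = q
        M[i, EP_ON] += s * p_rel
        nxt = REM_OFF[m] if m < TUNNEL_MONTHS else WELL
        M[i, nxt] += s * (1.0 - p_rel)

    # Well: recurrence restarts the original treatment.
    p_rec = annual_to_monthly_prob(config.annual_recurrence_prob)
    M[WELL, DEAD] = q
    M[WELL, EP_ON] = (1.0 - q) * p_rec
    M[WELL, WELL] = (1.0 - q) * (1.0 - p_rec)

    M[DEAD, DEAD] = 1.0

    row_sums = M.sum(axis=1)
    if not np.allclose(row_sums, 1.0, rtol=0.0, atol=_ROW_SUM_TOL):
        raise AssertionError(f"transition rows do not sum to 1: {row_sums}")
    return M


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy plus per-cycle accrual streams.

    ``occupancy`` has ``horizon + 1`` rows (row 0 is the start distribution);
    every stream has the same length with index 0 unused (accruals are booked
    at cycle end, cycles 1..horizon).  ``discontinuation_flow`` records the
    cohort mass newly moving from on- to off-treatment states each cycle.
    """

    occupancy: np.ndarray
    qaly_stream: np.ndarray
    direct_cost_stream: np.ndarray
    indirect_cost_stream: np.ndarray
    drug_cost_stream: np.ndarray
    adr_cost_stream: np.ndarray
    monitoring_cost_stream: np.ndarray
    discontinuation_flow: np.ndarray


def compute_cycle_accruals(
    occupancy_row: np.ndarray,
    profile: TreatmentProfile,
    config: ModelConfig,
    cycle: int,
    discontinuation_flow: float = 0.0,
) -> tuple[float, float, float, float, float, float]:
    """Accruals for one cycle from its end-of-cycle occupancy row.

    Returns ``(qaly, direct_cost, indirect_cost, drug_cost, adr_cost,
    monitoring_cost)``.  The indirect stream is always accrued; perspective
    is applied when arms are summarised.  ``discontinuation_flow`` is the
    mass that discontinued during this cycle and drives the one-time
    discontinuation-symptom disutility and management cost (booked into the
    ADR stream).
    """
    occ = np.asarray(occupancy_row, dtype=float)
    if abs(occ.sum() - 1.0) > 1e-6:
        raise ValidationError(f"occupancy row must sum to 1; got {occ.sum()!r}")
    sv = config.state_values
    econ = config.econ

    dis_episode = expected_adr_disutility(profile, config.adr_table, include_sleep=True)
    dis_remission = expected_adr_disutility(profile, config.adr_table, include_sleep=False)
    u_ep_on = max(0.0, sv.utility_episode - dis_episode)
    u_rem_on = max(0.0, sv.utility_remission - dis_remission)

    rem_on = occ[list(REM_ON)].sum()
    rem_off = occ[list(REM_OFF)].sum()
    qaly = (
        occ[EP_ON] * u_ep_on
        + rem_on * u_rem_on
        + occ[EP_OFF] * sv.utility_episode
        + rem_off * sv.utility_remission
        + occ[WELL] * sv.utility_well
    ) / 12.0
    symptom_fraction = econ.discontinuation_symptom_duration_days / econ.days_per_month
    qaly -= (
        discontinuation_flow
        * profile.discontinuation_symptom_prob
        * config.discontinuation_symptom_decrement
        * symptom_fraction
        / 12.0
    )

    episode_occ = occ[EP_ON] + occ[EP_OFF]
    remission_occ = rem_on + rem_off
    direct = episode_occ * sv.direct_cost_episode + remission_occ * sv.direct_cost_remission
    indirect = episode_occ * sv.indirect_cost_episode + remission_occ * sv.indirect_cost_remission

    on_occ = occ[EP_ON] + rem_on
    drug = on_occ * medication_cost(profile, cycle)

    adr = occ[EP_ON] * expected_adr_cost(profile, config.adr_table, include_sleep=True)
    adr += rem_on * expected_adr_cost(profile, config.adr_table, include_sleep=False)
    adr += discontinuation_flow * profile.discontinuation_symptom_prob * config.discontinuation_symptom_cost

    monitoring = 0.0
    if profile.hepatic_monitoring and cycle in HEPATIC_MONITORING_CYCLES:
        monitoring = on_occ * config.hepatic_test_cost

    return qaly, direct, indirect, drug, adr, monitoring


def run_cohort(profile: TreatmentProfile, config: ModelConfig) -> CohortTrace:
    """Run the cohort from unit mass in episode-on-treatment over the horizon."""
    horizon = config.econ.horizon_cycles
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, EP_ON] = 1.0
    streams = {
        name: np.zeros(horizon + 1)
        for name in ("qaly", "direct", "indirect", "drug", "adr", "monitoring", "flow")
    }
    on_idx = list(ON_TX_STATES)
    off_idx = list(OFF_TX_STATES)
    for t in range(horizon):
        age = config.econ.start_age_years + t / 12.0
        M = build_transition_matrix(profile, config, t, age)
        occ[t + 1] = occ[t] @ M
        flow = float(occ[t, on_idx] @ M[np.ix_(on_idx, off_idx)].sum(axis=1))
        cycle = t + 1
        qaly, direct, indirect, drug, adr, monitoring = compute_cycle_accruals(
            occ[cycle], profile, config, cycle, discontinuation_flow=flow
        )
        streams["qaly"][cycle] = qaly
        streams["direct"][cycle] = direct
        streams["indirect"][cycle] = indirect
        streams["drug"][cycle] = drug
        streams["adr"][cycle] = adr
        streams["monitoring"][cycle] = monitoring
        streams["flow"][cycle] = flow
    return CohortTrace(
        occupancy=occ,
        qaly_stream=streams["qaly"],
        direct_cost_stream=streams["direct"],
        indirect_cost_stream=streams["indirect"],
        drug_cost_stream=streams["drug"],
        adr_cost_stream=streams["adr"],
        monitoring_cost_stream=streams["monitoring"],
        discontinuation_flow=streams["flow"],
    )


def trace_to_frame(trace: CohortTrace) -> pd.DataFrame:
    """Trace as a DataFrame: one row per cycle, states then accrual streams."""
    df = pd.DataFrame(trace.occupancy, columns=STATE_NAMES)
    df.insert(0, "cycle", np.arange(len(df)))
    df["qaly"] = trace.qaly_stream
    df["direct_cost"] = trace.direct_cost_stream
    df["indirect_cost"] = trace.indirect_cost_stream
    df["drug_cost"] = trace.drug_cost_stream
    df["adr_cost"] = trace.adr_cost_stream
    df["monitoring_cost"] = trace.monitoring_cost_stream
    df["discontinuation_flow"] = trace.discontinuation_flow
    return df
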