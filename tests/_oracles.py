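"""Independent oracles used by the test suite.

These deliberately avoid the cohort-expectation code path they check: the
microsimulation samples individual patient trajectories from the same
one-cycle transition rules and estimates occupancy by counting.
"""

from __future__ import annotations

import numpy as np

from mddcea.markov_engine import (
    EP_ON,
    N_STATES,
    OFF_TX_STATES,
    ON_TX_STATES,
    build_transition_matrix,
    compute_cycle_accruals,
)


def microsimulate(profile, config, n: int, seed: int):
    """First-order microsimulation: occupancy fractions and discontinuation flows.

    Returns ``(occupancy, flows)`` where occupancy is (horizon+1, 16) in
    fractions and flows[c] is the fraction of patients newly moving from an
    on-treatment to an off-treatment state during cycle c.
    """
    rng = np.random.default_rng(seed)
    horizon = config.econ.horizon_cycles
    states = np.full(n, EP_ON, dtype=np.int64)
    occupancy = np.zeros((horizon + 1, N_STATES))
    occupancy[0] = np.bincount(states, minlength=N_STATES) / n
    flows = np.zeros(horizon + 1)
    on = np.array(ON_TX_STATES)
    off = np.array(OFF_TX_STATES)
    for t in range(horizon):
        age = config.econ.start_age_years + t / 12.0
        M = build_transition_matrix(profile, config, t, age)
        cum = np.cumsum(M, axis=1)
        u = rng.random(n)
        new_states = (u[:, None] > cum[states]).sum(axis=1)
        moved_off = np.isin(states, on) & np.isin(new_states, off)
        flows[t + 1] = moved_off.mean()
        states = new_states
        occupancy[t + 1] = np.bincount(states, minlength=N_STATES) / n
    return occupancy, flows


def microsim_totals(profile, config, n: int, seed: int):
    """Discounted QALY and cost totals from microsimulated occupancy."""
    from mddcea.economics import discount_factor

    occupancy, flows = microsimulate(profile, config, n, seed)
    horizon = config.econ.horizon_cycles
    rate = config.econ.annual_discount_rate
    qalys = 0.0
    cost = 0.0
    for c in range(1, horizon + 1):
        qaly, direct, indirect, drug, adr, monitoring = compute_cycle_accruals(
            occupancy[c], profile, config, c, discontinuation_flow=flows[c]
        )
        df = discount_factor(c, rate)
        qalys += df * qaly
        total = direct + drug + adr + monitoring
        if config.econ.perspective == "societal":
            total += indirect
        cost += df * total
    return qalys, cost
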