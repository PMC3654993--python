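import math

import numpy as np
import pytest

from mddcea import (
    RelapseSpec,
    ScenarioSeed,
    ValidationError,
    build_transition_matrix,
    compute_cycle_accruals,
    random_scenario,
    run_cohort,
    trace_to_frame,
    with_param,
)
from mddcea.markov_engine import (
    DEAD,
    EP_OFF,
    EP_ON,
    EPISODE_BOTH_EVENTS_STATE,
    HEPATIC_MONITORING_CYCLES,
    N_STATES,
    REM_OFF,
    REM_ON,
    REMISSION_BOTH_EVENTS_STATE,
    STATE_NAMES,
    WELL,
)


def _zero_mortality(config):
    config.mortality.life_table = {a: 0.0 for a in range(18, 101)}
    return config


def _no_relapse_spec():
    # scale so large the monthly relapse hazard is ~1e-12
    return RelapseSpec.weibull(1.0, 1e12)


class TestTransitionMatrix:
    def test_rows_are_stochastic_on_the_fixture(self, base_config):
        for t in base_config.treatments:
            M = build_transition_matrix(t, base_config, cycle=0, age=45.0)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, rtol=0, atol=1e-12)
            assert np.all(M >= 0)

    def test_zero_hazards_leave_only_tunnel_advancement(self, base_config):
        config = _zero_mortality(base_config)
        profile = config.treatment("Agomelatine")
        profile.monthly_remission_prob = 0.0
        profile.monthly_discontinuation_prob = 0.0
        profile.relapse = _no_relapse_spec()
        config.placebo_relapse = _no_relapse_spec()
        config.annual_recurrence_prob = 0.0
        config.off_treatment_remission_prob = 0.0
        M = build_transition_matrix(profile, config, cycle=0, age=45.0)
        expected = np.zeros((N_STATES, N_STATES))
        for i in (EP_ON, EP_OFF, WELL, DEAD):
            expected[i, i] = 1.0
        for m in range(6):
            expected[REM_ON[m], REM_ON[m + 1] if m < 5 else WELL] = 1.0
            expected[REM_OFF[m], REM_OFF[m + 1] if m < 5 else WELL] = 1.0
        np.testing.assert_allclose(M, expected, rtol=0, atol=1e-11)

    def test_episode_death_entry_matches_rate_scale_closed_form(self, base_config):
        profile = base_config.treatment("Venlafaxine")
        age = 52.0
        q_annual = base_config.mortality.life_table[52]
        q_month = 1.0 - (1.0 - q_annual) ** (1.0 / 12.0)
        expected = 1.0 - (1.0 - q_month) ** 20.35
        M = build_transition_matrix(profile, base_config, cycle=0, age=age)
        assert M[EP_ON, DEAD] == pytest.approx(expected, rel=1e-12)
        assert M[EP_OFF, DEAD] == pytest.approx(expected, rel=1e-12)
        # non-episode states carry plain background mortality
        assert M[WELL, DEAD] == pytest.approx(q_month, rel=1e-12)
        assert M[REM_ON[0], DEAD] == pytest.approx(q_month, rel=1e-12)

    def test_both_event_destinations_are_pinned(self, base_config):
        # remit-and-discontinue lands in the first off-treatment tunnel month;
        # relapse-and-discontinue returns to treatment
        assert EPISODE_BOTH_EVENTS_STATE == REM_OFF[0]
        assert REMISSION_BOTH_EVENTS_STATE == EP_ON
        profile = base_config.treatment("Venlafaxine")
        M = build_transition_matrix(profile, base_config, cycle=0, age=45.0)
        p_rem, p_disc = profile.monthly_remission_prob, profile.monthly_discontinuation_prob
        s = 1.0 - M[EP_ON, DEAD]
        assert M[EP_ON, REM_OFF[0]] == pytest.approx(s * p_rem * p_disc, rel=1e-12)

    def test_age_outside_life_table_raises(self, base_config):
        profile = base_config.treatments[0]
        with pytest.raises(ValidationError, match="life table"):
            build_transition_matrix(profile, base_config, cycle=0, age=150.0)


class TestRunCohort:
    def test_deterministic_remission_path_reaches_well_at_cycle_seven(self, base_config):
        config = _zero_mortality(base_config)
        profile = config.treatment("Agomelatine")
        profile.monthly_remission_prob = 1.0
        profile.monthly_discontinuation_prob = 0.0
        profile.relapse = _no_relapse_spec()
        trace = run_cohort(profile, config)
        # cycle 1 in remission month 1, ..., cycle 6 in month 6, cycle 7 well
        for m in range(6):
            assert trace.occupancy[1 + m, REM_ON[m]] == pytest.approx(1.0, abs=1e-9)
        assert trace.occupancy[7, WELL] == pytest.approx(1.0, abs=1e-9)

    def test_dead_occupancy_is_non_decreasing(self, base_config):
        trace = run_cohort(base_config.treatment("Agomelatine"), base_config)
        assert np.all(np.diff(trace.occupancy[:, DEAD]) >= -1e-15)

    def test_three_cycle_trace_matches_manual_forward_calculation(self, base_config):
        config = _zero_mortality(base_config)
        p_rel = 0.3
        profile = config.treatment("Agomelatine")
        profile.monthly_remission_prob = 0.5
        profile.monthly_discontinuation_prob = 0.2
        profile.relapse = RelapseSpec.weibull(1.0, -1.0 / math.log(1.0 - p_rel))
        config.placebo_relapse = RelapseSpec.weibull(1.0, -1.0 / math.log(1.0 - p_rel))
        config.off_treatment_remission_prob = 0.1
        config.annual_recurrence_prob = 0.0
        trace = run_cohort(profile, config)

        # manual forward pass with scalar arithmetic over the reachable states
        occ = {s: 0.0 for s in range(N_STATES)}
        occ[EP_ON] = 1.0
        for _ in range(3):
            new = {s: 0.0 for s in range(N_STATES)}
            new[REM_ON[0]] += occ[EP_ON] * 0.5 * 0.8
            new[EP_OFF] += occ[EP_ON] * 0.2 * 0.5
            new[REM_OFF[0]] += occ[EP_ON] * 0.5 * 0.2
            new[EP_ON] += occ[EP_ON] * 0.5 * 0.8
            for m in range(6):
                nxt = REM_ON[m + 1] if m < 5 else WELL
                new[EP_ON] += occ[REM_ON[m]] * p_rel
                new[REM_OFF[m]] += occ[REM_ON[m]] * 0.2 * (1 - p_rel)
                new[nxt] += occ[REM_ON[m]] * (1 - p_rel) * 0.8
            new[REM_OFF[0]] += occ[EP_OFF] * 0.1
            new[EP_OFF] += occ[EP_OFF] * 0.9
            for m in range(6):
                nxt = REM_OFF[m + 1] if m < 5 else WELL
                new[EP_ON] += occ[REM_OFF[m]] * p_rel
                new[nxt] += occ[REM_OFF[m]] * (1 - p_rel)
            occ = new
        for s in range(N_STATES):
            assert trace.occupancy[3, s] == pytest.approx(occ[s], abs=1e-12)

    def test_conservation_on_random_scenarios(self):
        for i in range(20):
            config = random_scenario(ScenarioSeed(rng_seed=100 + i, n_treatments=1))
            trace = run_cohort(config.treatments[0], config)
            np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, rtol=0, atol=1e-9)
            assert np.all(trace.occupancy >= -1e-15)

    def test_total_qalys_monotone_in_remission_probability(self, base_config):
        from mddcea import summarize_arm

        totals = []
        for p in np.linspace(0.1, 0.9, 9):
            config = with_param(base_config, "treatments.Agomelatine.monthly_remission_prob", float(p))
            profile = config.treatment("Agomelatine")
            totals.append(summarize_arm(run_cohort(profile, config), profile, config).total_qalys)
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))

    def test_trace_frame_has_documented_column_order(self, base_config):
        trace = run_cohort(base_config.treatments[0], base_config)
        df = trace_to_frame(trace)
        assert list(df.columns) == (
            ["cycle"] + STATE_NAMES + [
                "qaly", "direct_cost", "indirect_cost", "drug_cost",
                "adr_cost", "monitoring_cost", "discontinuation_flow",
            ]
        )
        assert len(df) == base_config.econ.horizon_cycles + 1


class TestCycleAccruals:
    def test_all_mass_dead_accrues_nothing(self, base_config):
        occ = np.zeros(N_STATES)
        occ[DEAD] = 1.0
        acc = compute_cycle_accruals(occ, base_config.treatments[0], base_config, cycle=1)
        assert acc == (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def test_all_mass_well_accrues_utility_only(self, base_config):
        occ = np.zeros(N_STATES)
        occ[WELL] = 1.0
        qaly, direct, indirect, drug, adr, monitoring = compute_cycle_accruals(
            occ, base_config.treatment("Venlafaxine"), base_config, cycle=1
        )
        assert qaly == pytest.approx(0.86 / 12.0, rel=1e-12)
        assert direct == indirect == drug == adr == monitoring == 0.0

    def test_episode_cycle_costs_match_hand_summed_components(self, base_config):
        profile = base_config.treatment("Venlafaxine")
        occ = np.zeros(N_STATES)
        occ[EP_ON] = 1.0
        qaly, direct, indirect, drug, adr, monitoring = compute_cycle_accruals(
            occ, profile, base_config, cycle=1
        )
        # hand-summed expected ADR management cost, sleep disorder included
        freq = {k.value: v for k, v in profile.adr_monthly_freq.items()}
        adr_expected = (
            freq["constipation"] * 12.5 + freq["dyspepsia"] * 12.0 + freq["diarrhoea"] * 5.5
            + freq["nausea"] * 6.0 + freq["somnolence"] * 0.0 + freq["headache"] * 2.8
            + freq["sexual_dysfunction"] * 44.0 + freq["sleep_disorder"] * 54.0
        )
        assert direct == pytest.approx(190.0)
        assert indirect == pytest.approx(380.0)
        assert drug == pytest.approx(18.03)
        assert adr == pytest.approx(adr_expected, rel=1e-12)
        assert monitoring == 0.0
        # payer-style direct cost of the cycle: state + drug + ADR management
        assert direct + drug + adr == pytest.approx(190.0 + 18.03 + adr_expected, rel=1e-12)

    def test_hepatic_monitoring_billed_at_the_four_test_cycles_only(self, base_config):
        trace = run_cohort(base_config.treatment("Agomelatine"), base_config)
        billed = np.nonzero(trace.monitoring_cost_stream)[0]
        assert set(billed) == set(HEPATIC_MONITORING_CYCLES)
        trace_v = run_cohort(base_config.treatment("Venlafaxine"), base_config)
        assert np.all(trace_v.monitoring_cost_stream == 0.0)

    def test_discontinuation_flow_drives_symptom_cost_and_disutility(self, base_config):
        profile = base_config.treatment("Venlafaxine")  # symptom prob 0.20
        occ = np.zeros(N_STATES)
        occ[EP_OFF] = 1.0
        base = compute_cycle_accruals(occ, profile, base_config, cycle=1, discontinuation_flow=0.0)
        with_flow = compute_cycle_accruals(occ, profile, base_config, cycle=1, discontinuation_flow=0.5)
        assert with_flow[4] - base[4] == pytest.approx(0.5 * 0.20 * 52.0, rel=1e-12)
        assert base[0] - with_flow[0] == pytest.approx(0.5 * 0.20 * 0.065 * (7.0 / 30.0) / 12.0, rel=1e-12)
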