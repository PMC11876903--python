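"""Microsimulation engine: probability plumbing, cohort, cycle mechanics."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hccsim.engine import (
    HealthState,
    annual_prob_to_cycle_prob,
    discounted_lifetime,
    draw_substrate,
    generate_cohort,
    mean_survival_to_cycle_mortality,
    simulate_arm,
    simulate_pair,
    step_patient,
)
from hccsim.parameters import (
    ModelParams,
    SimulationConfig,
    UnprintedParams,
    ValidationError,
)

S = HealthState


# ---------------------------------------------------------------------------
# probability conversions
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("p,cl,expected", [
    (0.0, 0.5, 0.0),
    (0.06, 1.0, 0.06),
    (0.06, 0.5, 1 - 0.94 ** 0.5),          # 0.0304640...
    (1.0, 0.25, 1.0),
])
def test_annual_prob_to_cycle_prob_closed_form(p, cl, expected):
    assert annual_prob_to_cycle_prob(p, cl) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("mean,cl,expected", [
    (2.0, 1.0, 1 - np.exp(-0.5)),           # 0.39346934
    (9.8, 0.5, 1 - np.exp(-0.5 / 9.8)),     # 0.049740...
    (np.inf, 0.5, 0.0),                     # immortal limit
])
def test_mean_survival_to_cycle_mortality_closed_form(mean, cl, expected):
    assert mean_survival_to_cycle_mortality(mean, cl) == pytest.approx(expected, abs=1e-12)


def test_mean_survival_rejects_nonpositive():
    with pytest.raises(ValidationError):
        mean_survival_to_cycle_mortality(0.0, 0.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(p=st.floats(0.0, 0.999), q=st.floats(0.0, 0.999),
       cl=st.sampled_from([0.25, 0.5, 1.0]))
def test_cycle_prob_monotone_in_both_arguments(p, q, cl):
    lo, hi = sorted((p, q))
    assert annual_prob_to_cycle_prob(lo, cl) <= annual_prob_to_cycle_prob(hi, cl)
    assert annual_prob_to_cycle_prob(p, cl / 2) <= annual_prob_to_cycle_prob(p, cl)


def test_discounted_lifetime_equals_mean_without_discounting():
    assert discounted_lifetime(6.5, 0.0) == pytest.approx(6.5)
    assert discounted_lifetime(6.5, 0.03) < 6.5


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def test_cohort_all_compensated_when_proportion_is_one(small_config):
    mp = ModelParams(prop_compensated=1.0)
    states = generate_cohort(small_config, mp, np.random.default_rng(0))
    assert (states == S.COMP_CIRRHOSIS).all()


def test_cohort_compensated_count_within_binomial_bound(base_params):
    config = SimulationConfig(n_patients=10_000, seed=5)
    states = generate_cohort(config, base_params, np.random.default_rng(5))
    n_comp = int((states == S.COMP_CIRRHOSIS).sum())
    bound = 3 * np.sqrt(10_000 * 0.58 * 0.42)
    assert abs(n_comp - 5_800) < bound


def test_cohort_reproducible_from_seed(small_config, base_params):
    a = generate_cohort(small_config, base_params, np.random.default_rng(9))
    b = generate_cohort(small_config, base_params, np.random.default_rng(9))
    assert (a == b).all()


# ---------------------------------------------------------------------------
# cycle mechanics
# ---------------------------------------------------------------------------

def _frozen_params() -> ModelParams:
    return ModelParams(p_decomp_annual=0.0, p_hcc_comp_annual=0.0,
                       p_hcc_decomp_annual=0.0,
                       surv_comp=np.inf, surv_decomp=np.inf,
                       surv_early_hcc=np.inf, surv_late_hcc=np.inf)


def test_frozen_chain_states_never_change(small_config, calib_unprinted):
    """With all transition probabilities zero the cohort is static."""
    res = simulate_arm("usual_care", small_config, _frozen_params(),
                       calib_unprinted, record_states=True)
    assert (res.states_trace == res.states_trace[0]).all()
    assert res.n_hcc == 0 and res.n_detected == 0


def test_one_cycle_event_frequencies_match_configured_probabilities(base_params,
                                                                    calib_unprinted):
    """Engine one-cycle event rates agree with the converted per-cycle
    probabilities within 3 standard errors at one million patients."""
    config = SimulationConfig(n_patients=1_000_000, horizon_years=0.5, seed=17)
    res = simulate_arm("usual_care", config, base_params, calib_unprinted)
    n_comp0 = int((res.baseline_state == S.COMP_CIRRHOSIS).sum())
    n_dec0 = config.n_patients - n_comp0

    q_c = mean_survival_to_cycle_mortality(9.8, 0.5)
    q_d = mean_survival_to_cycle_mortality(2.5, 0.5)
    p_dec = annual_prob_to_cycle_prob(0.06, 0.5)
    p_on_c = annual_prob_to_cycle_prob(0.02, 0.5)
    p_on_d = annual_prob_to_cycle_prob(0.04, 0.5)

    deaths = int(res.occupancy[1, S.DEAD])
    exp_deaths = n_comp0 * q_c + n_dec0 * q_d
    assert abs(deaths - exp_deaths) < 3 * np.sqrt(exp_deaths)

    onsets = res.n_hcc
    exp_at_c = n_comp0 * (1 - q_c) * (1 - p_dec)
    exp_at_d = n_dec0 * (1 - q_d) + n_comp0 * (1 - q_c) * p_dec
    exp_onsets = exp_at_c * p_on_c + exp_at_d * p_on_d
    assert abs(onsets - exp_onsets) < 3 * np.sqrt(exp_onsets)

    screens = res.total_screens
    exp_screens = config.n_patients * 0.23
    assert abs(screens - exp_screens) < 3 * np.sqrt(exp_screens * 0.77)


def test_state_count_conservation_every_cycle(small_config, base_params,
                                              calib_unprinted):
    for arm in ("outreach", "usual_care"):
        res = simulate_arm(arm, small_config, base_params, calib_unprinted)
        assert (res.occupancy.sum(axis=1) == small_config.n_patients).all()


def test_trace_obeys_allowed_transition_graph(base_params, calib_unprinted):
    """Detected states never revert, late never reverts to early, DEAD absorbs."""
    allowed = {
        S.COMP_CIRRHOSIS: {S.COMP_CIRRHOSIS, S.DECOMP_CIRRHOSIS,
                           S.HCC_EARLY_UNDETECTED, S.DEAD},
        S.DECOMP_CIRRHOSIS: {S.DECOMP_CIRRHOSIS, S.HCC_EARLY_UNDETECTED, S.DEAD},
        S.HCC_EARLY_UNDETECTED: {S.HCC_EARLY_UNDETECTED, S.HCC_LATE_UNDETECTED,
                                 S.HCC_EARLY_DETECTED, S.DEAD},
        S.HCC_LATE_UNDETECTED: {S.HCC_LATE_UNDETECTED, S.HCC_LATE_DETECTED, S.DEAD},
        S.HCC_EARLY_DETECTED: {S.HCC_EARLY_DETECTED, S.DEAD},
        S.HCC_LATE_DETECTED: {S.HCC_LATE_DETECTED, S.DEAD},
        S.DEAD: {S.DEAD},
    }
    config = SimulationConfig(n_patients=3_000, seed=3)
    for accrual in ("lifetime", "horizon"):
        conf = dataclasses.replace(config, accrual=accrual)
        res = simulate_arm("outreach", conf, base_params, calib_unprinted,
                           record_states=True)
        trace = res.states_trace
        for t in range(trace.shape[0] - 1):
            pairs = set(zip(trace[t].tolist(), trace[t + 1].tolist()))
            for a, b in pairs:
                assert S(b) in allowed[S(a)], f"{S(a).name} -> {S(b).name}"


def test_horizon_accrual_qaly_bounded_by_horizon(base_params, calib_unprinted):
    config = SimulationConfig(n_patients=3_000, seed=8, accrual="horizon")
    res = simulate_arm("outreach", config, base_params, calib_unprinted)
    assert (res.qaly <= config.horizon_years + 1e-9).all()
    assert (res.qaly >= 0).all()


def test_zero_horizon_yields_zero_outcomes(base_params, calib_unprinted):
    config = SimulationConfig(n_patients=500, horizon_years=0.0, seed=1)
    res = simulate_arm("outreach", config, base_params, calib_unprinted)
    assert res.total_cost == 0.0 and res.total_qaly == 0.0
    assert res.n_hcc == 0 and res.total_screens == 0


def test_simulation_bit_identical_for_same_seed(small_config, base_params,
                                                calib_unprinted):
    a = simulate_arm("outreach", small_config, base_params, calib_unprinted)
    b = simulate_arm("outreach", small_config, base_params, calib_unprinted)
    assert a.total_cost == b.total_cost and a.total_qaly == b.total_qaly
    assert (a.cost == b.cost).all() and (a.qaly == b.qaly).all()
    assert (a.detection_cycle == b.detection_cycle).all()


def test_identical_arms_give_exactly_zero_deltas(base_params, calib_unprinted):
    """With equal adherence and zero outreach cost, common random numbers
    make the two arms byte-identical."""
    mp = dataclasses.replace(base_params, adherence_outreach=0.23,
                             outreach_cost_y1=0.0, outreach_cost_later=0.0)
    config = SimulationConfig(n_patients=5_000, seed=21)
    out, usual = simulate_pair(config, mp, calib_unprinted)
    assert out.total_cost == usual.total_cost
    assert out.total_qaly == usual.total_qaly
    assert out.n_early_detected == usual.n_early_detected


def test_early_detection_monotone_in_outreach_adherence(base_params,
                                                        calib_unprinted):
    """More adherence can only find more early tumors under shared streams."""
    config = SimulationConfig(n_patients=5_000, seed=13)
    sub = draw_substrate(config)
    counts = []
    for adherence in (0.10, 0.23, 0.35, 0.60, 0.90):
        mp = dataclasses.replace(base_params, adherence_outreach=adherence)
        res = simulate_arm("outreach", config, mp, calib_unprinted, sub)
        counts.append(res.n_early_detected)
    assert counts == sorted(counts)


def test_detected_counts_are_consistent(small_config, base_params, calib_unprinted):
    res = simulate_arm("outreach", small_config, base_params, calib_unprinted)
    assert res.n_early_detected + res.n_late_detected == res.n_detected
    assert res.n_detected <= res.n_hcc
    assert res.n_terminal_detected <= res.n_late_detected


# ---------------------------------------------------------------------------
# single-patient reference step
# ---------------------------------------------------------------------------

class TestStepPatient:
    def test_dead_input_violates_precondition(self, base_params, calib_unprinted):
        with pytest.raises(ValidationError):
            step_patient(S.DEAD, "outreach", 0, base_params, calib_unprinted,
                         np.random.default_rng(0))

    def test_every_living_state_steps_to_an_allowed_state(self, base_params,
                                                          calib_unprinted):
        rng = np.random.default_rng(2)
        for state in [s for s in S if s != S.DEAD]:
            for _ in range(50):
                nxt, events = step_patient(state, "usual_care", 0, base_params,
                                           calib_unprinted, rng)
                assert isinstance(nxt, S)
                if state in (S.HCC_EARLY_DETECTED, S.HCC_LATE_DETECTED):
                    assert nxt in (state, S.DEAD)

    def test_frozen_chain_is_static(self, calib_unprinted):
        rng = np.random.default_rng(3)
        frozen = _frozen_params()
        up = dataclasses.replace(calib_unprinted, p_incidental_early_percycle=0.0,
                                 p_symptomatic_detect_percycle=0.0,
                                 screen_sensitivity_early=0.0)
        mp = dataclasses.replace(frozen, adherence_usual=0.0)
        for state in (S.COMP_CIRRHOSIS, S.DECOMP_CIRRHOSIS, S.HCC_LATE_UNDETECTED):
            for _ in range(20):
                nxt, _ev = step_patient(state, "usual_care", 0, mp, up, rng)
                assert nxt == state

    def test_early_detection_frequency_matches_configuration(self, base_params,
                                                             calib_unprinted):
        """Hazard of early detection = adherence x sensitivity joined with
        the incidental channel, within 3 SE."""
        rng = np.random.default_rng(4)
        n = 20_000
        detected = 0
        for _ in range(n):
            nxt, ev = step_patient(S.HCC_EARLY_UNDETECTED, "outreach", 0,
                                   base_params, calib_unprinted, rng, tumor_age=0)
            detected += ev["detected"] == "early"
        a_s = 0.35 * calib_unprinted.screen_sensitivity_early
        p = a_s + (1 - a_s) * calib_unprinted.p_incidental_early_percycle
        assert abs(detected - n * p) < 3 * np.sqrt(n * p * (1 - p))
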