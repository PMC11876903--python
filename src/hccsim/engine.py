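"""Per-patient state-transition microsimulation of HCC screening in cirrhosis.

The engine follows individual patients with cirrhosis through semi-annual
cycles of cirrhosis natural history (compensated -> decompensated, with
liver-related mortality), HCC onset (annual incidence 2% compensated / 4%
decompensated converted to per-cycle probabilities), undetected tumor
progression (early -> late after a calibrated dwell time), screening
(arm-specific per-cycle adherence, early-stage sensitivity), incidental and
symptomatic detection, and QALY/cost accrual discounted at 3% per year.

Within each cycle, events are applied in a fixed documented order:

1. tumor aging and early->late progression,
2. outreach-program charge (outreach arm, all undiagnosed alive patients),
3. screening / incidental / symptomatic detection (with treatment-episode
   cost and -- in ``lifetime`` accrual mode -- the expected discounted
   post-diagnosis QALY lump),
4. state-specific mortality with half-cycle-corrected utility and care-cost
   accrual,
5. decompensation and HCC onset among survivors.

Detection deliberately precedes the mortality draw: patients dying of
advanced HCC present clinically and are diagnosed at terminal presentation
rather than dying with the tumor never counted.

All per-patient randomness is drawn up front into a :class:`RandomSubstrate`
(one uniform per patient x cycle x event channel), so the two strategy arms
can consume *identical* streams (common random numbers): arm differences
then isolate the effect of adherence and program cost rather than noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

from .parameters import ModelParams, SimulationConfig, UnprintedParams, ValidationError

__all__ = [
    "HealthState",
    "RandomSubstrate",
    "ArmResult",
    "annual_prob_to_cycle_prob",
    "mean_survival_to_cycle_mortality",
    "discounted_lifetime",
    "generate_cohort",
    "draw_substrate",
    "step_patient",
    "simulate_arm",
    "simulate_pair",
]


class HealthState(IntEnum):
    COMP_CIRRHOSIS = 0
    DECOMP_CIRRHOSIS = 1
    HCC_EARLY_UNDETECTED = 2
    HCC_LATE_UNDETECTED = 3
    HCC_EARLY_DETECTED = 4
    HCC_LATE_DETECTED = 5
    DEAD = 6


# event-channel layout of the random substrate
_ADHERE, _SENS, _INCID, _SYMPT, _FP, _DEATH, _DECOMP, _ONSET = range(8)
N_CHANNELS = 8


# ---------------------------------------------------------------------------
# probability plumbing
# ---------------------------------------------------------------------------

def annual_prob_to_cycle_prob(p_annual: float, cycle_length: float) -> float:
    """Convert an annual transition probability to a per-cycle probability.

    Assumes a constant hazard within the year: ``1 - (1-p)**cycle_length``.
    """
    if not (0.0 <= p_annual <= 1.0):
        raise ValidationError(f"p_annual {p_annual} outside [0, 1]")
    if cycle_length <= 0:
        raise ValidationError("cycle_length must be > 0")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** cycle_length


def mean_survival_to_cycle_mortality(mean_survival: float, cycle_length: float) -> float:
    """Per-cycle death probability for exponential survival with given mean."""
    if mean_survival <= 0:
        raise ValidationError("mean_survival must be > 0")
    if cycle_length <= 0:
        raise ValidationError("cycle_length must be > 0")
    return 1.0 - float(np.exp(-cycle_length / mean_survival))


def discounted_lifetime(mean_survival: float, annual_rate: float) -> float:
    """Expected discounted years lived, exponential survival, continuous discounting.

    ``E[int_0^T e^{-rho t} dt] = 1/(lambda + rho)`` with ``lambda = 1/mean``
    and ``rho = ln(1 + annual_rate)`` the continuous equivalent of the annual
    discount rate.
    """
    if mean_survival <= 0:
        raise ValidationError("mean_survival must be > 0")
    lam = 1.0 / mean_survival
    rho = float(np.log1p(annual_rate))
    return 1.0 / (lam + rho)


# ---------------------------------------------------------------------------
# cohort and randomness
# ---------------------------------------------------------------------------

@dataclass
class RandomSubstrate:
    """Pre-drawn uniforms shared by both arms for common random numbers."""

    baseline: np.ndarray          # (n,) baseline-state uniforms
    events: np.ndarray            # (n, n_cycles, N_CHANNELS) event uniforms

    @property
    def n_patients(self) -> int:
        return self.baseline.shape[0]


def draw_substrate(config: SimulationConfig, seed: Optional[int] = None) -> RandomSubstrate:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n, c = config.n_patients, config.n_cycles
    return RandomSubstrate(
        baseline=rng.random(n),
        events=rng.random((n, c, N_CHANNELS)),
    )


def generate_cohort(config: SimulationConfig, params: ModelParams,
                    rng_or_substrate) -> np.ndarray:
    """Baseline states: compensated w.p. ``prop_compensated`` else decompensated."""
    if isinstance(rng_or_substrate, RandomSubstrate):
        u = rng_or_substrate.baseline
    else:
        u = rng_or_substrate.random(config.n_patients)
    states = np.where(u < params.prop_compensated,
                      np.int8(HealthState.COMP_CIRRHOSIS),
                      np.int8(HealthState.DECOMP_CIRRHOSIS))
    return states.astype(np.int8)


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class ArmResult:
    """Aggregate and per-patient outcome of one simulated strategy arm."""

    arm: str
    n_patients: int
    total_cost: float
    total_qaly: float
    n_hcc: int
    n_detected: int
    n_early_detected: int
    n_late_detected: int          # includes terminal (at-death) diagnoses
    n_terminal_detected: int
    total_screens: int
    occupancy: np.ndarray                  # (n_cycles+1, 7) state counts
    cost: np.ndarray = field(repr=False)   # per-patient discounted cost
    qaly: np.ndarray = field(repr=False)   # per-patient discounted QALY
    baseline_state: np.ndarray = field(repr=False)
    onset_cycle: np.ndarray = field(repr=False)      # -1 if never
    detection_cycle: np.ndarray = field(repr=False)  # -1 if never
    detected_stage: np.ndarray = field(repr=False)   # 0 none, 1 early, 2 late
    terminal_dx: np.ndarray = field(repr=False)      # diagnosed at death
    screens_completed: np.ndarray = field(repr=False)
    states_trace: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def per_patient_cost(self) -> float:
        return self.total_cost / self.n_patients

    @property
    def per_patient_qaly(self) -> float:
        return self.total_qaly / self.n_patients

    def trajectories(self) -> pd.DataFrame:
        """One row per patient (baseline state, detection, accruals)."""
        return pd.DataFrame({
            "patient_id": np.arange(self.n_patients),
            "baseline_state": [HealthState(int(s)).name for s in self.baseline_state],
            "onset_cycle": self.onset_cycle,
            "detection_cycle": self.detection_cycle,
            "detected_stage": np.array(["none", "early", "late"])[self.detected_stage],
            "terminal_diagnosis": self.terminal_dx,
            "screens_completed": self.screens_completed,
            "discounted_cost": self.cost,
            "discounted_qaly": self.qaly,
        })

    def summary(self) -> dict:
        return {
            "arm": self.arm,
            "n_patients": self.n_patients,
            "total_cost": float(self.total_cost),
            "total_qaly": float(self.total_qaly),
            "per_patient_cost": float(self.per_patient_cost),
            "per_patient_qaly": float(self.per_patient_qaly),
            "n_hcc": int(self.n_hcc),
            "n_detected": int(self.n_detected),
            "n_early_detected": int(self.n_early_detected),
            "n_late_detected": int(self.n_late_detected),
            "n_terminal_detected": int(self.n_terminal_detected),
            "total_screens": int(self.total_screens),
        }


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _cycle_probs(params: ModelParams, config: SimulationConfig) -> dict:
    cl = config.cycle_length
    return {
        "decomp": annual_prob_to_cycle_prob(params.p_decomp_annual, cl),
        "onset_comp": annual_prob_to_cycle_prob(params.p_hcc_comp_annual, cl),
        "onset_decomp": annual_prob_to_cycle_prob(params.p_hcc_decomp_annual, cl),
        "die_comp": mean_survival_to_cycle_mortality(params.surv_comp, cl),
        "die_decomp": mean_survival_to_cycle_mortality(params.surv_decomp, cl),
        "die_early": mean_survival_to_cycle_mortality(params.surv_early_hcc, cl),
        "die_late": mean_survival_to_cycle_mortality(params.surv_late_hcc, cl),
    }


def _qaly_lumps(params: ModelParams) -> tuple[float, float]:
    return (
        params.utility_early_hcc * discounted_lifetime(params.surv_early_hcc,
                                                       params.discount_qaly),
        params.utility_late_hcc * discounted_lifetime(params.surv_late_hcc,
                                                      params.discount_qaly),
    )


def outreach_annuities(params: ModelParams,
                       config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Expected discounted within-horizon program cost after a diagnosis.

    Outreach is mailed to every alive patient; in ``lifetime`` accrual mode
    diagnosed patients leave the cycle loop, so their remaining program cost
    is charged at diagnosis as an expected discounted annuity at the
    later-years rate, with stage-specific exponential survival.  The
    detection cycle itself is charged per-cycle, so the annuity runs from
    the end of that cycle to the horizon, valued relative to the cycle
    midpoint.  Returns (early, late) arrays indexed by detection cycle.
    """
    cl = config.cycle_length
    t_mid = (np.arange(config.n_cycles) + 0.5) * cl
    rho_c = float(np.log1p(params.discount_cost))
    remaining = np.maximum(config.horizon_years - (t_mid + 0.5 * cl), 0.0)
    out = []
    for surv in (params.surv_early_hcc, params.surv_late_hcc):
        lam = 1.0 / surv + rho_c
        out.append(params.outreach_cost_later * np.exp(-lam * 0.5 * cl)
                   * (1.0 - np.exp(-lam * remaining)) / lam)
    return out[0], out[1]


def resolution_values(params: ModelParams, unprinted: UnprintedParams,
                      config: SimulationConfig) -> dict:
    """Expected discounted continuation of an undiagnosed tumor at the horizon.

    Post-horizon there is no organized screening in either arm; early tumors
    are found incidentally, late tumors symptomatically, deaths in undetected
    states are terminal presentations (when ``terminal_diagnosis`` is on).
    Returns per-unit-mass expected cost and QALY, valued at the horizon, for
    a late tumor (``cost_late``/``qaly_late``) and for an early tumor with
    ``m`` early-stage cycles remaining (arrays indexed by m = 0..dwell).
    """
    cl = config.cycle_length
    dwell = int(unprinted.early_dwell_cycles)
    q_e = mean_survival_to_cycle_mortality(params.surv_early_hcc, cl)
    q_l = mean_survival_to_cycle_mortality(params.surv_late_hcc, cl)
    pi = unprinted.p_incidental_early_percycle
    ps = unprinted.p_symptomatic_detect_percycle
    lump_e, lump_l = _qaly_lumps(params)
    workup = unprinted.cost_diagnostic_workup * unprinted.cpi_adjust
    term = (params.cost_treat_late + workup) if config.terminal_diagnosis else 0.0
    b_c = (1.0 + params.discount_cost) ** (-cl)
    b_q = (1.0 + params.discount_qaly) ** (-cl)
    m_c, m_q = b_c ** 0.5, b_q ** 0.5
    u_e, u_l = params.utility_early_hcc, params.utility_late_hcc

    # late stage: symptomatic detection w.p. ps, else death w.p. q_l, else wait
    stay_l = (1.0 - ps) * (1.0 - q_l)
    VL_c = m_c * (ps * (params.cost_treat_late + workup) + (1.0 - ps) * q_l * term) \
        / (1.0 - b_c * stay_l)
    VL_q = m_q * (ps * lump_l + (1.0 - ps) * (0.5 * q_l + (1.0 - q_l)) * u_l * cl) \
        / (1.0 - b_q * stay_l)

    VE_c = np.zeros(dwell + 1)
    VE_q = np.zeros(dwell + 1)
    VE_c[0], VE_q[0] = VL_c, VL_q
    for m in range(1, dwell + 1):
        VE_c[m] = m_c * (pi * (params.cost_treat_early + workup)
                         + (1.0 - pi) * q_e * term) \
            + b_c * (1.0 - pi) * (1.0 - q_e) * VE_c[m - 1]
        VE_q[m] = m_q * (pi * lump_e + (1.0 - pi) * (0.5 * q_e + (1.0 - q_e)) * u_e * cl) \
            + b_q * (1.0 - pi) * (1.0 - q_e) * VE_q[m - 1]
    return {"cost_early": VE_c, "qaly_early": VE_q,
            "cost_late": VL_c, "qaly_late": VL_q}


def simulate_arm(arm: str, config: SimulationConfig, params: ModelParams,
                 unprinted: UnprintedParams,
                 substrate: Optional[RandomSubstrate] = None,
                 record_states: bool = False) -> ArmResult:
    """Simulate one strategy arm over the full horizon.

    ``arm`` is ``"outreach"`` or ``"usual_care"``.  With a shared
    ``substrate`` the two arms consume identical random streams.
    """
    if arm not in ("outreach", "usual_care"):
        raise ValidationError(f"arm: unknown arm {arm!r}")
    config.validate(); params.validate(); unprinted.validate()
    if substrate is None:
        substrate = draw_substrate(config)

    n, n_cycles = config.n_patients, config.n_cycles
    cl = config.cycle_length
    u = substrate.events
    probs = _cycle_probs(params, config)
    adherence = params.adherence_outreach if arm == "outreach" else params.adherence_usual
    lump_early, lump_late = _qaly_lumps(params)
    lifetime = config.accrual == "lifetime"
    mechanistic = config.detection_mode == "mechanistic"
    dwell = int(unprinted.early_dwell_cycles)
    cpi = unprinted.cpi_adjust
    care_rate = np.array([unprinted.cost_care_comp_annual,
                          unprinted.cost_care_decomp_annual]) * cpi
    workup = unprinted.cost_diagnostic_workup * cpi

    t_mid = (np.arange(n_cycles) + 0.5) * cl
    disc_c = (1.0 + params.discount_cost) ** (-t_mid)
    disc_q = (1.0 + params.discount_qaly) ** (-t_mid)
    annuity_early, annuity_late = outreach_annuities(params, config)
    util = np.array([params.utility_comp, params.utility_decomp,
                     params.utility_early_hcc, params.utility_late_hcc,
                     params.utility_early_hcc, params.utility_late_hcc, 0.0])
    die_p = np.array([probs["die_comp"], probs["die_decomp"],
                      probs["die_early"], probs["die_late"],
                      probs["die_early"], probs["die_late"], 0.0])

    state = generate_cohort(config, params, substrate).copy()
    decomp_flag = (state == HealthState.DECOMP_CIRRHOSIS)
    baseline_state = state.copy()
    tumor_age = np.full(n, -1, dtype=np.int32)      # -1: no tumor
    onset_cycle = np.full(n, -1, dtype=np.int32)
    detection_cycle = np.full(n, -1, dtype=np.int32)
    detected_stage = np.zeros(n, dtype=np.int8)     # 0 none / 1 early / 2 late
    screens = np.zeros(n, dtype=np.int32)
    cost = np.zeros(n)
    qaly = np.zeros(n)
    exited = np.zeros(n, dtype=bool)                # lifetime mode: diagnosed & credited
    terminal_dx = np.zeros(n, dtype=bool)

    occupancy = np.zeros((n_cycles + 1, 7), dtype=np.int64)
    trace = np.zeros((n_cycles + 1, n), dtype=np.int8) if record_states else None

    def snapshot(row: int) -> None:
        occupancy[row] = np.bincount(state, minlength=7)
        if trace is not None:
            trace[row] = state

    for t in range(n_cycles):
        # 1. tumor aging and progression (tumors present at cycle start)
        has_tumor = tumor_age >= 0
        tumor_age[has_tumor] += 1
        progress = (state == HealthState.HCC_EARLY_UNDETECTED) & (tumor_age > dwell)
        state[progress] = HealthState.HCC_LATE_UNDETECTED
        snapshot(t)

        alive = state != HealthState.DEAD
        undiag = alive & (state <= HealthState.HCC_LATE_UNDETECTED) & ~exited

        # 2. outreach-program charge (population mailing: every alive
        #    patient, regardless of adherence or diagnosis)
        if arm == "outreach":
            rate = params.outreach_cost_y1 if t * cl < 1.0 else params.outreach_cost_later
            cost[alive & ~exited] += rate * cl * disc_c[t]

        # 3. screening and detection
        adherent = undiag & (u[:, t, _ADHERE] < adherence)
        screens[adherent] += 1
        if mechanistic:
            early_und = undiag & (state == HealthState.HCC_EARLY_UNDETECTED)
            det_screen = early_und & adherent & (u[:, t, _SENS] < unprinted.screen_sensitivity_early)
            det_incid = early_und & ~det_screen & (
                u[:, t, _INCID] < unprinted.p_incidental_early_percycle)
            det_early = det_screen | det_incid
            det_late = undiag & (state == HealthState.HCC_LATE_UNDETECTED) & (
                u[:, t, _SYMPT] < unprinted.p_symptomatic_detect_percycle)
            false_pos = adherent & (state <= HealthState.DECOMP_CIRRHOSIS) & (
                u[:, t, _FP] < unprinted.p_false_positive)
            cost[false_pos] += workup * disc_c[t]

            state[det_early] = HealthState.HCC_EARLY_DETECTED
            state[det_late] = HealthState.HCC_LATE_DETECTED
            newly = det_early | det_late
            detection_cycle[newly] = t
            detected_stage[det_early] = 1
            detected_stage[det_late] = 2
            cost[det_early] += (params.cost_treat_early + workup) * disc_c[t]
            cost[det_late] += (params.cost_treat_late + workup) * disc_c[t]
            if lifetime:
                qaly[det_early] += lump_early * disc_q[t]
                qaly[det_late] += lump_late * disc_q[t]
                if arm == "outreach":
                    cost[det_early] += annuity_early[t] * disc_c[t]
                    cost[det_late] += annuity_late[t] * disc_c[t]
                exited[newly] = True

        # 4. mortality + half-cycle-corrected accrual
        active = (state != HealthState.DEAD) & ~exited
        dies = active & (u[:, t, _DEATH] < die_p[state])
        w = np.where(dies, 0.5, 1.0)
        acc = active
        qaly[acc] += util[state[acc]] * cl * w[acc] * disc_q[t]
        pre_dx = acc & (state <= HealthState.HCC_LATE_UNDETECTED)
        cost[pre_dx] += care_rate[decomp_flag[pre_dx].astype(int)] * cl * w[pre_dx] * disc_c[t]
        if config.terminal_diagnosis:
            # terminal presentation: death with an undiagnosed tumor incurs
            # the late-stage episode cost and counts as a late diagnosis
            terminal = dies & (state == HealthState.HCC_EARLY_UNDETECTED) | \
                dies & (state == HealthState.HCC_LATE_UNDETECTED)
            cost[terminal] += (params.cost_treat_late + workup) * disc_c[t]
            detection_cycle[terminal] = t
            detected_stage[terminal] = 2
            terminal_dx[terminal] = True
        state[dies] = HealthState.DEAD

        # 5. transitions among undiagnosed survivors
        survivors = (state != HealthState.DEAD) & ~exited
        comp = survivors & (state == HealthState.COMP_CIRRHOSIS)
        to_decomp = comp & (u[:, t, _DECOMP] < probs["decomp"])
        state[to_decomp] = HealthState.DECOMP_CIRRHOSIS
        decomp_flag[to_decomp] = True

        at_risk_c = survivors & (state == HealthState.COMP_CIRRHOSIS)
        at_risk_d = survivors & (state == HealthState.DECOMP_CIRRHOSIS)
        onset = ((at_risk_c & (u[:, t, _ONSET] < probs["onset_comp"])) |
                 (at_risk_d & (u[:, t, _ONSET] < probs["onset_decomp"])))
        onset_cycle[onset] = t
        tumor_age[onset] = 0
        if mechanistic:
            state[onset] = HealthState.HCC_EARLY_UNDETECTED
        else:
            # reduced form: stage assigned at diagnosis, which coincides with
            # onset, from the published early-detection probabilities
            # conditional on this cycle's screening status
            p_early = np.where(adherent[onset], params.p_early_with_screen,
                               params.p_early_without_screen)
            early = u[onset, t, _INCID] < p_early
            idx = np.flatnonzero(onset)
            e_idx, l_idx = idx[early], idx[~early]
            state[e_idx] = HealthState.HCC_EARLY_DETECTED
            state[l_idx] = HealthState.HCC_LATE_DETECTED
            detection_cycle[idx] = t
            detected_stage[e_idx] = 1
            detected_stage[l_idx] = 2
            cost[e_idx] += (params.cost_treat_early + workup) * disc_c[t]
            cost[l_idx] += (params.cost_treat_late + workup) * disc_c[t]
            if lifetime:
                qaly[e_idx] += lump_early * disc_q[t]
                qaly[l_idx] += lump_late * disc_q[t]
                if arm == "outreach":
                    cost[e_idx] += annuity_early[t] * disc_c[t]
                    cost[l_idx] += annuity_late[t] * disc_c[t]
                exited[idx] = True

    # final snapshot reflects the state entering the (hypothetical) next
    # cycle: apply the aging/progression step once more
    has_tumor = tumor_age >= 0
    tumor_age[has_tumor] += 1
    progress = (state == HealthState.HCC_EARLY_UNDETECTED) & (tumor_age > dwell)
    state[progress] = HealthState.HCC_LATE_UNDETECTED
    snapshot(n_cycles)

    if lifetime and config.resolve_horizon and mechanistic:
        res = resolution_values(params, unprinted, config)
        disc_h_c = (1.0 + params.discount_cost) ** (-config.horizon_years)
        disc_h_q = (1.0 + params.discount_qaly) ** (-config.horizon_years)
        early_left = state == HealthState.HCC_EARLY_UNDETECTED
        late_left = state == HealthState.HCC_LATE_UNDETECTED
        # an early tumor entering its a-th detectable cycle has
        # m = dwell - a + 1 early-stage cycles remaining
        m = np.clip(dwell - tumor_age[early_left] + 1, 0, dwell)
        cost[early_left] += res["cost_early"][m] * disc_h_c
        qaly[early_left] += res["qaly_early"][m] * disc_h_q
        cost[late_left] += res["cost_late"] * disc_h_c
        qaly[late_left] += res["qaly_late"] * disc_h_q

    return ArmResult(
        arm=arm,
        n_patients=n,
        total_cost=float(cost.sum()),
        total_qaly=float(qaly.sum()),
        n_hcc=int((onset_cycle >= 0).sum()),
        n_detected=int((detected_stage > 0).sum()),
        n_early_detected=int((detected_stage == 1).sum()),
        n_late_detected=int((detected_stage == 2).sum()),
        n_terminal_detected=int(terminal_dx.sum()),
        total_screens=int(screens.sum()),
        occupancy=occupancy,
        cost=cost,
        qaly=qaly,
        baseline_state=baseline_state,
        onset_cycle=onset_cycle,
        detection_cycle=detection_cycle,
        detected_stage=detected_stage,
        terminal_dx=terminal_dx,
        screens_completed=screens,
        states_trace=trace,
    )


def simulate_pair(config: SimulationConfig, params: ModelParams,
                  unprinted: UnprintedParams,
                  seed: Optional[int] = None) -> tuple[ArmResult, ArmResult]:
    """Simulate outreach and usual-care arms, sharing randomness under CRN."""
    base_seed = config.seed if seed is None else seed
    sub = draw_substrate(config, seed=base_seed)
    if config.use_common_random_numbers:
        sub2 = sub
    else:
        sub2 = draw_substrate(config, seed=base_seed + 1)
    outreach = simulate_arm("outreach", config, params, unprinted, sub)
    usual = simulate_arm("usual_care", config, params, unprinted, sub2)
    return outreach, usual


# ---------------------------------------------------------------------------
# single-patient reference step
# ---------------------------------------------------------------------------

def step_patient(state: HealthState, arm: str, cycle: int, params: ModelParams,
                 unprinted: UnprintedParams, rng: np.random.Generator,
                 tumor_age: int = 0, cycle_length: float = 0.5) -> tuple[HealthState, dict]:
    """Advance one undiagnosed patient by one cycle; returns (state, events).

    Reference scalar implementation of the engine's cycle, in the same event
    order (progression, detection, mortality, decompensation, onset).  DEAD
    input violates the precondition.
    """
    if state == HealthState.DEAD:
        raise ValidationError("step_patient: patient is DEAD (absorbing)")
    params.validate(); unprinted.validate()
    adherence = params.adherence_outreach if arm == "outreach" else params.adherence_usual
    cl = cycle_length
    events = {"screened": False, "detected": None, "died": False,
              "decompensated": False, "onset": False, "progressed": False}

    # progression of an existing tumor
    if state == HealthState.HCC_EARLY_UNDETECTED and tumor_age + 1 > unprinted.early_dwell_cycles:
        state = HealthState.HCC_LATE_UNDETECTED
        events["progressed"] = True

    if state <= HealthState.HCC_LATE_UNDETECTED:
        if rng.random() < adherence:
            events["screened"] = True
        if state == HealthState.HCC_EARLY_UNDETECTED:
            det = (events["screened"] and rng.random() < unprinted.screen_sensitivity_early)
            if not det:
                det = rng.random() < unprinted.p_incidental_early_percycle
            if det:
                events["detected"] = "early"
                return HealthState.HCC_EARLY_DETECTED, events
        elif state == HealthState.HCC_LATE_UNDETECTED:
            if rng.random() < unprinted.p_symptomatic_detect_percycle:
                events["detected"] = "late"
                return HealthState.HCC_LATE_DETECTED, events

    die_p = {
        HealthState.COMP_CIRRHOSIS: mean_survival_to_cycle_mortality(params.surv_comp, cl),
        HealthState.DECOMP_CIRRHOSIS: mean_survival_to_cycle_mortality(params.surv_decomp, cl),
        HealthState.HCC_EARLY_UNDETECTED: mean_survival_to_cycle_mortality(params.surv_early_hcc, cl),
        HealthState.HCC_LATE_UNDETECTED: mean_survival_to_cycle_mortality(params.surv_late_hcc, cl),
        HealthState.HCC_EARLY_DETECTED: mean_survival_to_cycle_mortality(params.surv_early_hcc, cl),
        HealthState.HCC_LATE_DETECTED: mean_survival_to_cycle_mortality(params.surv_late_hcc, cl),
    }[state]
    if rng.random() < die_p:
        events["died"] = True
        return HealthState.DEAD, events

    if state == HealthState.COMP_CIRRHOSIS:
        if rng.random() < annual_prob_to_cycle_prob(params.p_decomp_annual, cl):
            state = HealthState.DECOMP_CIRRHOSIS
            events["decompensated"] = True
    if state == HealthState.COMP_CIRRHOSIS:
        if rng.random() < annual_prob_to_cycle_prob(params.p_hcc_comp_annual, cl):
            state = HealthState.HCC_EARLY_UNDETECTED
            events["onset"] = True
    elif state == HealthState.DECOMP_CIRRHOSIS:
        if rng.random() < annual_prob_to_cycle_prob(params.p_hcc_decomp_annual, cl):
            state = HealthState.HCC_EARLY_UNDETECTED
            events["onset"] = True
    return state, events
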