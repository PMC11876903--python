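"""Deterministic cohort-expectation oracle.

Propagates expected state occupancy forward over the same per-cycle
probabilities and event ordering as the microsimulation engine, with the
early-stage dwell time expanded into per-age sub-compartments and the
underlying cirrhosis state (for care costs) tracked alongside undetected
tumors.  Because every quantity is an exact expectation, the oracle serves
two purposes:

* a validation oracle -- microsimulation means must converge to it as the
  cohort grows (tested at n = 200,000 within 3 standard errors);
* a noise-free, millisecond-fast objective for calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import (
    annual_prob_to_cycle_prob,
    mean_survival_to_cycle_mortality,
    outreach_annuities,
    resolution_values,
    _qaly_lumps,
)
from .parameters import ModelParams, SimulationConfig, UnprintedParams, ValidationError

__all__ = ["ExpectedOutcomes", "expected_outcomes"]


@dataclass
class ExpectedOutcomes:
    """Expected (cohort-mean x n_patients) outcomes of one strategy arm."""

    arm: str
    n_patients: int
    occupancy: np.ndarray        # (n_cycles+1, 7) expected state counts
    onsets: np.ndarray           # (n_cycles,) expected HCC onsets per cycle
    det_early: np.ndarray        # (n_cycles,) expected early-stage diagnoses
    det_late: np.ndarray         # (n_cycles,) expected late-stage diagnoses (pre-terminal)
    det_terminal: np.ndarray     # (n_cycles,) expected terminal (at-death) diagnoses
    screens: np.ndarray          # (n_cycles,) expected completed screens
    at_risk_comp: np.ndarray     # (n_cycles,) at-risk mass when onset prob applies
    at_risk_decomp: np.ndarray
    total_cost: float
    total_qaly: float

    @property
    def n_hcc(self) -> float:
        return float(self.onsets.sum())

    @property
    def n_early_detected(self) -> float:
        return float(self.det_early.sum())

    @property
    def n_late_detected(self) -> float:
        return float(self.det_late.sum() + self.det_terminal.sum())

    @property
    def n_terminal_detected(self) -> float:
        return float(self.det_terminal.sum())

    @property
    def n_detected(self) -> float:
        return self.n_early_detected + self.n_late_detected

    @property
    def per_patient_cost(self) -> float:
        return self.total_cost / self.n_patients

    @property
    def per_patient_qaly(self) -> float:
        return self.total_qaly / self.n_patients


def expected_outcomes(arm: str, config: SimulationConfig, params: ModelParams,
                      unprinted: UnprintedParams) -> ExpectedOutcomes:
    """Exact forward propagation of the cohort expectation for one arm."""
    if arm not in ("outreach", "usual_care"):
        raise ValidationError(f"arm: unknown arm {arm!r}")
    config.validate(); params.validate(); unprinted.validate()

    n_cycles = config.n_cycles
    cl = config.cycle_length
    n = config.n_patients
    adh = params.adherence_outreach if arm == "outreach" else params.adherence_usual
    mechanistic = config.detection_mode == "mechanistic"
    lifetime = config.accrual == "lifetime"
    dwell = int(unprinted.early_dwell_cycles)
    cpi = unprinted.cpi_adjust
    care = np.array([unprinted.cost_care_comp_annual,
                     unprinted.cost_care_decomp_annual]) * cpi
    workup = unprinted.cost_diagnostic_workup * cpi
    lump_e, lump_l = _qaly_lumps(params)

    p_dec = annual_prob_to_cycle_prob(params.p_decomp_annual, cl)
    p_on_c = annual_prob_to_cycle_prob(params.p_hcc_comp_annual, cl)
    p_on_d = annual_prob_to_cycle_prob(params.p_hcc_decomp_annual, cl)
    q_c = mean_survival_to_cycle_mortality(params.surv_comp, cl)
    q_d = mean_survival_to_cycle_mortality(params.surv_decomp, cl)
    q_e = mean_survival_to_cycle_mortality(params.surv_early_hcc, cl)
    q_l = mean_survival_to_cycle_mortality(params.surv_late_hcc, cl)

    # detection hazard while early-stage undetected: screen then incidental
    h_e = adh * unprinted.screen_sensitivity_early
    h_e = h_e + (1.0 - h_e) * unprinted.p_incidental_early_percycle
    ps = unprinted.p_symptomatic_detect_percycle

    t_mid = (np.arange(n_cycles) + 0.5) * cl
    disc_c = (1.0 + params.discount_cost) ** (-t_mid)
    disc_q = (1.0 + params.discount_qaly) ** (-t_mid)

    u_c, u_d = params.utility_comp, params.utility_decomp
    u_e, u_l = params.utility_early_hcc, params.utility_late_hcc

    C = n * params.prop_compensated
    D = n * (1.0 - params.prop_compensated)
    E = np.zeros((dwell + 1, 2))     # rows: tumor age 1..dwell (row 0 unused)
    L = np.zeros(2)                  # underlying comp / decomp
    detE = detL = dead = 0.0

    occupancy = np.zeros((n_cycles + 1, 7))
    onsets = np.zeros(n_cycles)
    det_e_t = np.zeros(n_cycles)
    det_l_t = np.zeros(n_cycles)
    det_t_t = np.zeros(n_cycles)
    screens = np.zeros(n_cycles)
    at_c = np.zeros(n_cycles)
    at_d = np.zeros(n_cycles)
    total_cost = 0.0
    total_qaly = 0.0

    def snap(row: int) -> None:
        occupancy[row] = (C, D, E.sum(), L.sum(), detE, detL, dead)

    ann_early, ann_late = outreach_annuities(params, config)

    for t in range(n_cycles):
        snap(t)
        undiag = C + D + E.sum() + L.sum()

        if arm == "outreach":
            rate = params.outreach_cost_y1 if t * cl < 1.0 else params.outreach_cost_later
            alive_mass = undiag if lifetime else undiag + detE + detL
            total_cost += alive_mass * rate * cl * disc_c[t]

        screens[t] = adh * undiag

        if mechanistic:
            fE = E * h_e
            fL = L * ps
            det_e_t[t] = fE.sum()
            det_l_t[t] = fL.sum()
            E = E * (1.0 - h_e)
            L = L * (1.0 - ps)
            total_cost += (C + D) * adh * unprinted.p_false_positive * workup * disc_c[t]
            total_cost += det_e_t[t] * (params.cost_treat_early + workup) * disc_c[t]
            total_cost += det_l_t[t] * (params.cost_treat_late + workup) * disc_c[t]
            if lifetime:
                total_qaly += (det_e_t[t] * lump_e + det_l_t[t] * lump_l) * disc_q[t]
                if arm == "outreach":
                    total_cost += (det_e_t[t] * ann_early[t]
                                   + det_l_t[t] * ann_late[t]) * disc_c[t]
            # detected mass joins the (frozen in lifetime mode) DET compartments
            detE += det_e_t[t]
            detL += det_l_t[t]
        else:
            det_e_t[t] = det_l_t[t] = 0.0  # reduced form: diagnosis at onset below

        # mortality + half-cycle-corrected accrual
        for mass, q, util, flag in ((C, q_c, u_c, 0), (D, q_d, u_d, 1)):
            total_qaly += mass * (1.0 - 0.5 * q) * util * cl * disc_q[t]
            total_cost += mass * (1.0 - 0.5 * q) * care[flag] * cl * disc_c[t]
        for flag in (0, 1):
            total_qaly += E[:, flag].sum() * (1.0 - 0.5 * q_e) * u_e * cl * disc_q[t]
            total_cost += E[:, flag].sum() * (1.0 - 0.5 * q_e) * care[flag] * cl * disc_c[t]
            total_qaly += L[flag] * (1.0 - 0.5 * q_l) * u_l * cl * disc_q[t]
            total_cost += L[flag] * (1.0 - 0.5 * q_l) * care[flag] * cl * disc_c[t]
        if not lifetime:
            total_qaly += detE * (1.0 - 0.5 * q_e) * u_e * cl * disc_q[t]
            total_qaly += detL * (1.0 - 0.5 * q_l) * u_l * cl * disc_q[t]

        if config.terminal_diagnosis and mechanistic:
            # terminal presentation of deaths in undetected HCC states
            det_t_t[t] = E.sum() * q_e + L.sum() * q_l
            total_cost += det_t_t[t] * (params.cost_treat_late + workup) * disc_c[t]
        dead += (C * q_c + D * q_d + E.sum() * q_e + L.sum() * q_l)
        C_s, D_s = C * (1.0 - q_c), D * (1.0 - q_d)
        E = E * (1.0 - q_e)
        L = L * (1.0 - q_l)
        if not lifetime:
            dead += detE * q_e + detL * q_l
            detE *= (1.0 - q_e)
            detL *= (1.0 - q_l)

        # decompensation, then onset at the post-decompensation state's rate
        flow_dec = C_s * p_dec
        C2 = C_s - flow_dec
        D2 = D_s + flow_dec
        oC = C2 * p_on_c
        oD = D2 * p_on_d
        at_c[t], at_d[t] = C2, D2
        onsets[t] = oC + oD
        C = C2 - oC
        D = D2 - oD

        if mechanistic:
            E_next = np.zeros_like(E)
            E_next[1, 0] = oC
            E_next[1, 1] = oD
            if dwell >= 2:
                E_next[2:dwell + 1] = E[1:dwell]
            L = L + E[dwell]
            E = E_next
        else:
            mix = adh * params.p_early_with_screen + (1.0 - adh) * params.p_early_without_screen
            fe, fl = onsets[t] * mix, onsets[t] * (1.0 - mix)
            det_e_t[t] = fe
            det_l_t[t] = fl
            total_cost += (fe * (params.cost_treat_early + workup) +
                           fl * (params.cost_treat_late + workup)) * disc_c[t]
            if lifetime:
                total_qaly += (fe * lump_e + fl * lump_l) * disc_q[t]
                if arm == "outreach":
                    total_cost += (fe * ann_early[t] + fl * ann_late[t]) * disc_c[t]
            detE += fe
            detL += fl

    snap(n_cycles)

    if lifetime and config.resolve_horizon and mechanistic:
        res = resolution_values(params, unprinted, config)
        disc_h_c = (1.0 + params.discount_cost) ** (-config.horizon_years)
        disc_h_q = (1.0 + params.discount_qaly) ** (-config.horizon_years)
        # E row a holds tumors entering their a-th detectable cycle next:
        # m = dwell - a + 1 early-stage cycles remain
        for a in range(1, dwell + 1):
            mass = E[a].sum()
            m = dwell - a + 1
            total_cost += mass * res["cost_early"][m] * disc_h_c
            total_qaly += mass * res["qaly_early"][m] * disc_h_q
        total_cost += L.sum() * res["cost_late"] * disc_h_c
        total_qaly += L.sum() * res["qaly_late"] * disc_h_q

    return ExpectedOutcomes(
        arm=arm, n_patients=n, occupancy=occupancy, onsets=onsets,
        det_early=det_e_t, det_late=det_l_t, det_terminal=det_t_t,
        screens=screens,
        at_risk_comp=at_c, at_risk_decomp=at_d,
        total_cost=float(total_cost), total_qaly=float(total_qaly),
    )
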