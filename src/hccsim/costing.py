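"""Micro-costing of the mailed-outreach program and patient out-of-pocket costs.

The outreach program was costed bottom-up from activity time logs kept during
a 2,872-patient pragmatic trial (1,436 patients in the outreach arm, 18
months of outreach per patient): chart review for eligibility, program
management, computer support, language services, letter supplies and staff
time for calls and mailings.  This module reproduces that ledger arithmetic
(per-patient total, first-year and later-year annualized costs), models the
patient perspective (travel and lost wages per completed screen), and
provides a scalar reference implementation of the per-trajectory discounted
cost/QALY accrual used to cross-check the vectorized engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import HealthState, _qaly_lumps
from .parameters import ModelParams, SimulationConfig, UnprintedParams, ValidationError

__all__ = [
    "LineItem",
    "CostLedger",
    "PatientCostParams",
    "load_ledger",
    "default_ledger",
    "per_patient_total",
    "annualize",
    "patient_oop_per_screen",
    "expected_annual_oop",
    "accrue_costs",
    "accrue_qalys",
]

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class LineItem:
    activity: str
    total_cost: float
    hours: Optional[float] = None
    one_time: bool = False

    def __post_init__(self):
        if self.total_cost < 0:
            raise ValidationError(f"line item {self.activity!r}: cost must be >= 0")


@dataclass
class CostLedger:
    """Outreach-program cost ledger (all amounts 2021 US dollars).

    ``window_months`` is the period of outreach the dollar totals reflect
    (18 months per patient in the source trial); annualization prorates to
    12 months.  One-time items (eligibility chart review, language
    transcription and validation) are excluded from later-year costs.
    """

    items: list = field(default_factory=list)
    trial_n: int = 2872
    outreach_arm_n: int = 1436
    window_months: float = 18.0

    def validate(self) -> "CostLedger":
        if self.window_months <= 0:
            raise ValidationError("window_months: must be > 0")
        if self.outreach_arm_n > self.trial_n:
            raise ValidationError("outreach_arm_n: cannot exceed trial_n")
        for item in self.items:
            if item.total_cost < 0:
                raise ValidationError(f"{item.activity}: cost must be >= 0")
        return self

    @property
    def total_cost(self) -> float:
        return sum(i.total_cost for i in self.items)

    @property
    def recurring_cost(self) -> float:
        return sum(i.total_cost for i in self.items if not i.one_time)

    def scaled(self, factor: float) -> "CostLedger":
        items = [LineItem(i.activity, i.total_cost * factor, i.hours, i.one_time)
                 for i in self.items]
        return CostLedger(items, self.trial_n, self.outreach_arm_n, self.window_months)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "activity": [i.activity for i in self.items],
            "hours": [i.hours for i in self.items],
            "total_cost": [i.total_cost for i in self.items],
            "one_time": [i.one_time for i in self.items],
        })

    def report(self) -> dict:
        first, later = annualize(self)
        return {
            "total_cost": round(self.total_cost, 2),
            "n_patients_trial": self.trial_n,
            "n_patients_outreach_arm": self.outreach_arm_n,
            "window_months": self.window_months,
            "cost_per_patient": round(per_patient_total(self), 2),
            "annual_cost_per_patient_first_year": round(first, 2),
            "annual_cost_per_patient_later_years": round(later, 2),
        }


def load_ledger(path, trial_n: int = 2872, outreach_arm_n: int = 1436,
                window_months: float = 18.0) -> CostLedger:
    """Read a ledger CSV (columns activity, hours, total_cost, one_time)."""
    df = pd.read_csv(path)
    required = {"activity", "total_cost"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ledger CSV: missing column(s) {sorted(missing)}")
    items = []
    for idx, row in df.iterrows():
        try:
            hours = None if "hours" not in df.columns or pd.isna(row.get("hours")) \
                else float(row["hours"])
            items.append(LineItem(
                activity=str(row["activity"]),
                total_cost=float(row["total_cost"]),
                hours=hours,
                one_time=bool(int(row["one_time"])) if "one_time" in df.columns else False,
            ))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"ledger CSV row {idx} ({row.get('activity')!r}): {exc}")
    return CostLedger(items, trial_n, outreach_arm_n, window_months).validate()


def default_ledger() -> CostLedger:
    """The shipped trial micro-costing ledger."""
    return load_ledger(_DATA / "outreach_ledger.csv")


def per_patient_total(ledger: CostLedger) -> float:
    """Total program cost divided by the number of outreach-arm patients."""
    if ledger.outreach_arm_n <= 0:
        raise ValidationError("outreach_arm_n: must be > 0")
    return ledger.total_cost / ledger.outreach_arm_n


def annualize(ledger: CostLedger) -> tuple[float, float]:
    """(first-year, later-year) per-patient annual costs.

    The ledger reflects ``window_months`` of outreach; both figures prorate
    to 12 months, and later years drop the one-time set-up items.
    """
    ledger.validate()
    scale = 12.0 / ledger.window_months
    first = per_patient_total(ledger) * scale
    later = ledger.recurring_cost / ledger.outreach_arm_n * scale
    return first, later


# ---------------------------------------------------------------------------
# patient perspective
# ---------------------------------------------------------------------------

@dataclass
class PatientCostParams:
    """Out-of-pocket cost drivers for one screening ultrasound visit.

    Default wage is an approximate 2021 Dallas-area mean hourly wage
    (BLS OEWS scale) with the fringe-benefits rate applied to lost wages.
    """

    mileage_rate: float = 0.16       # USD per mile
    roundtrip_miles: float = 20.0
    employment_rate: float = 0.30
    hours_per_visit: float = 3.0
    hourly_wage: float = 28.50       # USD/hour, 2021 dollars
    benefits_rate: float = 0.276

    def validate(self) -> "PatientCostParams":
        for name in ("mileage_rate", "roundtrip_miles", "hours_per_visit",
                     "hourly_wage", "benefits_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name}: must be >= 0")
        if not (0.0 <= self.employment_rate <= 1.0):
            raise ValidationError("employment_rate: must lie in [0, 1]")
        return self


def patient_oop_per_screen(p: PatientCostParams) -> float:
    """Expected out-of-pocket cost of one completed screening visit.

    Travel (mileage x roundtrip distance) plus expected lost wages
    (employment rate x hours x loaded wage).
    """
    p.validate()
    travel = p.mileage_rate * p.roundtrip_miles
    wages = p.employment_rate * p.hours_per_visit * p.hourly_wage * (1.0 + p.benefits_rate)
    return travel + wages


def expected_annual_oop(p: PatientCostParams, adherence: float,
                        screens_per_year: Optional[float] = None) -> float:
    """Expected annual out-of-pocket cost per patient at a given adherence.

    ``screens_per_year`` defaults to the adherence value itself, i.e. one
    counted screening opportunity per year -- the annualized completed-
    screening rate the source program costing implies (see methods note).
    Pass ``2 * adherence`` for strict semi-annual opportunity accounting.
    """
    if screens_per_year is None:
        screens_per_year = adherence
    return patient_oop_per_screen(p) * screens_per_year


# ---------------------------------------------------------------------------
# per-trajectory reference accrual
# ---------------------------------------------------------------------------

def _underlying_decomp(states: Sequence[int], t: int, start_flag: bool) -> bool:
    # underlying cirrhosis state: decompensated once DECOMP observed pre-onset
    if start_flag:
        return True
    for s in states[:t + 1]:
        if s == HealthState.DECOMP_CIRRHOSIS:
            return True
    return False


def accrue_costs(states: Sequence[int], detection_cycle: int, detected_stage: int,
                 arm: str, params: ModelParams, unprinted: UnprintedParams,
                 config: SimulationConfig, onset_cycle: int = -1,
                 terminal: bool = False) -> float:
    """Discounted health-system cost of one patient trajectory.

    Scalar reference implementation mirroring the engine cycle-for-cycle:
    outreach charge while undiagnosed and alive (outreach arm only), cirrhosis
    care costs with half-cycle correction for the death cycle, the
    stage-specific treatment episode plus diagnostic workup at detection
    (including terminal presentation at death with an undiagnosed tumor), and
    the analytic resolution of tumors undiagnosed at the horizon, all
    discounted to cycle midpoints.  False-positive workups are excluded
    (they depend on draws not recoverable from the state sequence).
    """
    from .engine import outreach_annuities, resolution_values

    params.validate(); unprinted.validate(); config.validate()
    cl = config.cycle_length
    lifetime = config.accrual == "lifetime"
    care = (unprinted.cost_care_comp_annual * unprinted.cpi_adjust,
            unprinted.cost_care_decomp_annual * unprinted.cpi_adjust)
    workup = unprinted.cost_diagnostic_workup * unprinted.cpi_adjust
    treat = (None, params.cost_treat_early, params.cost_treat_late)
    ann = (None,) + tuple(outreach_annuities(params, config)) \
        if config.n_cycles else (None, None, None)
    cost = 0.0
    for t in range(config.n_cycles):
        s = int(states[t])
        if s == HealthState.DEAD:
            break
        disc = (1.0 + params.discount_cost) ** (-(t + 0.5) * cl)
        undiag = s <= HealthState.HCC_LATE_UNDETECTED
        detected_now = (t == detection_cycle)
        died = int(states[t + 1]) == HealthState.DEAD
        if arm == "outreach" and (undiag or not lifetime):
            # population mailing reaches every alive patient; in lifetime
            # mode post-diagnosis cycles are covered by the annuity below
            rate = params.outreach_cost_y1 if t * cl < 1.0 else params.outreach_cost_later
            cost += rate * cl * disc
        if detected_now:
            cost += (treat[detected_stage] + workup) * disc
            if lifetime and not (terminal and died):
                if arm == "outreach":
                    cost += ann[detected_stage][t] * disc
                break
        if undiag and (not detected_now or (terminal and died)):
            # terminal diagnoses still accrue the half-cycle of
            # pre-diagnosis care
            w = 0.5 if died else 1.0
            flag = int(_underlying_decomp(states, t, False))
            cost += care[flag] * cl * w * disc
    else:
        s_end = int(states[config.n_cycles])
        if (lifetime and config.resolve_horizon
                and s_end in (HealthState.HCC_EARLY_UNDETECTED,
                              HealthState.HCC_LATE_UNDETECTED)):
            res = resolution_values(params, unprinted, config)
            disc_h = (1.0 + params.discount_cost) ** (-config.horizon_years)
            if s_end == HealthState.HCC_LATE_UNDETECTED:
                cost += res["cost_late"] * disc_h
            else:
                age = config.n_cycles - 1 - onset_cycle
                m = max(0, min(int(unprinted.early_dwell_cycles),
                               int(unprinted.early_dwell_cycles) - age))
                cost += res["cost_early"][m] * disc_h
    return cost


def accrue_qalys(states: Sequence[int], detection_cycle: int, detected_stage: int,
                 params: ModelParams, unprinted: UnprintedParams,
                 config: SimulationConfig, onset_cycle: int = -1,
                 terminal: bool = False) -> float:
    """Discounted QALYs of one patient trajectory (reference implementation).

    In ``lifetime`` accrual mode, diagnosis credits the stage-specific
    expected discounted post-diagnosis QALYs as a lump (terminal diagnoses
    credit only the half-cycle of pre-death utility), and tumors undiagnosed
    at the horizon are resolved analytically; otherwise per-cycle stage
    utilities are accrued to death or horizon with half-cycle correction.
    """
    from .engine import resolution_values

    params.validate(); config.validate()
    cl = config.cycle_length
    lifetime = config.accrual == "lifetime"
    lump_e, lump_l = _qaly_lumps(params)
    lump = (None, lump_e, lump_l)
    util = {
        int(HealthState.COMP_CIRRHOSIS): params.utility_comp,
        int(HealthState.DECOMP_CIRRHOSIS): params.utility_decomp,
        int(HealthState.HCC_EARLY_UNDETECTED): params.utility_early_hcc,
        int(HealthState.HCC_LATE_UNDETECTED): params.utility_late_hcc,
        int(HealthState.HCC_EARLY_DETECTED): params.utility_early_hcc,
        int(HealthState.HCC_LATE_DETECTED): params.utility_late_hcc,
    }
    qaly = 0.0
    for t in range(config.n_cycles):
        s = int(states[t])
        if s == HealthState.DEAD:
            break
        disc = (1.0 + params.discount_qaly) ** (-(t + 0.5) * cl)
        died = int(states[t + 1]) == HealthState.DEAD
        if t == detection_cycle and lifetime and not (terminal and died):
            qaly += lump[detected_stage] * disc
            break
        # accrual state: non-terminal detection switches the stage utility
        # mid-cycle; terminal diagnoses die in their undetected state
        s_acc = s
        if t == detection_cycle and not terminal:
            s_acc = int(HealthState.HCC_EARLY_DETECTED) if detected_stage == 1 \
                else int(HealthState.HCC_LATE_DETECTED)
        w = 0.5 if died else 1.0
        qaly += util[s_acc] * cl * w * disc
    else:
        s_end = int(states[config.n_cycles])
        if (lifetime and config.resolve_horizon
                and s_end in (HealthState.HCC_EARLY_UNDETECTED,
                              HealthState.HCC_LATE_UNDETECTED)):
            res = resolution_values(params, unprinted, config)
            disc_h = (1.0 + params.discount_qaly) ** (-config.horizon_years)
            if s_end == HealthState.HCC_LATE_UNDETECTED:
                qaly += res["qaly_late"] * disc_h
            else:
                age = config.n_cycles - 1 - onset_cycle
                m = max(0, min(int(unprinted.early_dwell_cycles),
                               int(unprinted.early_dwell_cycles) - age))
                qaly += res["qaly_early"][m] * disc_h
    return qaly
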