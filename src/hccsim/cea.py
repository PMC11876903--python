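"""Cost-effectiveness comparison of paired strategy arms.

Standard incremental analysis: cost and QALY deltas between the outreach
and usual-care arms, strong-dominance classification, and the incremental
cost-effectiveness ratio (ICER) judged against a willingness-to-pay
threshold (default $100,000 per QALY).  Under strong dominance (cheaper and
more effective, or the reverse) no ICER is reported, following standard CEA
practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

from .engine import ArmResult
from .oracle import ExpectedOutcomes
from .parameters import ValidationError

__all__ = ["CEAComparison", "compare_arms", "relative_early_increase", "table3_report"]

DEFAULT_WTP = 100_000.0

ArmLike = Union[ArmResult, ExpectedOutcomes]


@dataclass
class CEAComparison:
    """Incremental result of outreach versus usual care."""

    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    verdict: str                 # dominant | dominated | icer_below_wtp | icer_above_wtp
    wtp: float = DEFAULT_WTP

    def as_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "verdict": self.verdict,
            "wtp": self.wtp,
        }


def compare_arms(outreach: ArmLike, usual: ArmLike,
                 wtp: float = DEFAULT_WTP) -> CEAComparison:
    """Classify the outreach-vs-usual-care comparison.

    Dominant: outreach costs less and yields more QALYs (no ICER).
    Dominated: the reverse.  Otherwise the ICER ``delta_cost/delta_qaly``
    is classified against the willingness-to-pay threshold.
    """
    if outreach.n_patients != usual.n_patients:
        raise ValidationError(
            f"compare_arms: cohort sizes differ "
            f"({outreach.n_patients} vs {usual.n_patients})")
    dc = outreach.total_cost - usual.total_cost
    dq = outreach.total_qaly - usual.total_qaly
    if dc < 0 and dq > 0:
        return CEAComparison(dc, dq, None, "dominant", wtp)
    if dc > 0 and dq < 0:
        return CEAComparison(dc, dq, None, "dominated", wtp)
    if dq == 0:
        # no effect difference: cost-only comparison, ICER undefined
        verdict = "dominant" if dc < 0 else ("dominated" if dc > 0 else "icer_below_wtp")
        return CEAComparison(dc, dq, None, verdict, wtp)
    icer = dc / dq
    if dq < 0:
        # less effective and cheaper: ICER is savings forgone per QALY lost;
        # classify by whether forgoing is acceptable at the threshold
        verdict = "icer_below_wtp" if icer > wtp else "icer_above_wtp"
    else:
        verdict = "icer_below_wtp" if icer <= wtp else "icer_above_wtp"
    return CEAComparison(dc, dq, icer, verdict, wtp)


def relative_early_increase(outreach: ArmLike, usual: ArmLike) -> float:
    """Relative increase in early-stage detections, outreach vs usual care."""
    if usual.n_early_detected <= 0:
        return math.nan
    return (outreach.n_early_detected - usual.n_early_detected) / usual.n_early_detected


def table3_report(outreach: ArmLike, usual: ArmLike,
                  wtp: float = DEFAULT_WTP) -> dict:
    """JSON-ready summary in the published cost-effectiveness table layout."""
    cmp = compare_arms(outreach, usual, wtp)
    def row(a: ArmLike) -> dict:
        return {
            "cost": a.total_cost,
            "qaly": a.total_qaly,
            "per_patient_cost": a.per_patient_cost,
            "per_patient_qaly": a.per_patient_qaly,
        }
    return {
        "outreach": row(outreach),
        "usual_care": row(usual),
        "difference": {
            "cost": cmp.delta_cost,
            "qaly": cmp.delta_qaly,
            "per_patient_cost": cmp.delta_cost / outreach.n_patients,
            "per_patient_qaly": cmp.delta_qaly / outreach.n_patients,
        },
        "icer": cmp.icer,
        "verdict": cmp.verdict,
        "wtp": wtp,
        "early_detected": {
            "outreach": float(outreach.n_early_detected),
            "usual_care": float(usual.n_early_detected),
            "relative_increase": relative_early_increase(outreach, usual),
        },
    }
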