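"""Micro-costing of the outreach program and the patient's own costs.

The program ledger tracks staff time and materials for 1,436 outreach-arm
patients over 18 months of outreach; annualizing prorates to 12 months and
drops one-time set-up items (eligibility chart review, language services)
from later years.  The patient perspective adds travel and lost wages per
completed screening visit.
"""

from hccsim import (
    PatientCostParams,
    annualize,
    default_ledger,
    expected_annual_oop,
    patient_oop_per_screen,
    per_patient_total,
)

ledger = default_ledger()
print("Outreach program ledger")
for item in ledger.items:
    tag = " (one-time)" if item.one_time else ""
    print(f"  {item.activity:<55} ${item.total_cost:>10,.2f}{tag}")
print(f"  {'TOTAL':<55} ${ledger.total_cost:>10,.2f}")

first, later = annualize(ledger)
print(f"\nper outreach-arm patient (18 months): ${per_patient_total(ledger):.2f}")
print(f"annualized, first year:  ${first:.2f}  (includes one-time set-up)")
print(f"annualized, later years: ${later:.2f}")

p = PatientCostParams()
print(f"\npatient out-of-pocket per completed screen: "
      f"${patient_oop_per_screen(p):.2f} "
      f"(travel ${p.mileage_rate * p.roundtrip_miles:.2f} + expected lost wages)")
print(f"expected annual out-of-pocket at outreach adherence (0.35): "
      f"${expected_annual_oop(p, adherence=0.35):.2f}")
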