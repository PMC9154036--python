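"""Renal-function work-up for a single patient.

Computes the Cockcroft-Gault clearance on the dosing weight (the lower of
measured and Devine ideal body weight), the CKD-EPI eGFR, and the percent
progression between the last two eGFR values — the quantities displayed
with every renal alert.  A ClCG at or below 30 mL/min is what fires the
DOAC/colchicine/metformin renal rules.
"""

from pharmacheck import (
    ckd_epi,
    cockcroft_gault,
    delta_egfr_percent,
    dosing_weight,
    ideal_body_weight,
    Sex,
)

age, sex = 80, Sex.male
height_cm, weight_measured = 170.0, 92.0
creatinine_umol_l = 170.0

ibw = ideal_body_weight(height_cm, sex)
selected = dosing_weight(weight_measured, ibw)
clcg = cockcroft_gault(age, selected, creatinine_umol_l, sex)
egfr = ckd_epi(creatinine_umol_l, age, sex)
delta = delta_egfr_percent(50.0, 57.0)  # last two published eGFR values

print(f"ideal body weight     : {ibw:.1f} kg")
print(f"dosing weight         : {selected:.1f} kg (lower of {weight_measured} and {ibw:.1f})")
print(f"Cockcroft-Gault ClCG  : {clcg:.1f} mL/min")
print(f"CKD-EPI eGFR          : {egfr:.1f} mL/min/1.73m2")
print(f"delta eGFR (50 -> 57) : {delta:+.0f} %")
print(f"renal-rule trigger    : {'YES (ClCG <= 30)' if clcg <= 30 else 'no'}")
# The ClCG on the 66 kg ideal weight is far lower than it would be on the
# 92 kg measured weight — exactly why the lower weight is the safe choice.
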