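"""Non-invasive WK3 estimate from cuff pressure, heart rate and mean flow.

The only inputs are routine clinic numbers: brachial SBP/DBP, heart rate,
and the artery's mean flow (from Doppler, or a flow-diameter power law).
The cohort-median normalized parameters are rescaled to the patient's own
Rtot and cardiac period.
"""

from windkessel3 import (ClinicalScalars, FlowDiameterLaw,
                         estimate_wk3_noninvasive, mean_arterial_pressure)

clinical = ClinicalScalars(sbp=120, dbp=80, heart_rate=63, artery="cca",
                           mean_flow=458 / 60)  # 458 mL/min -> mL/s
params = estimate_wk3_noninvasive(clinical)

print(f"MAP  = {mean_arterial_pressure(120, 80):.2f} mmHg")
print(f"T    = {clinical.period:.3f} s")
print(f"Rtot = {params.rtot:.2f} mmHg s/mL")
print(f"R1 = {params.r1:.3f}  R2 = {params.r2:.2f} mmHg s/mL   C = {params.c:.4f} mL/mmHg")

# Same estimate when mean flow comes from a lumen diameter via Q = k * D^b
# (coefficients are study-specific and must be supplied):
law = FlowDiameterLaw(k=0.212, b=2.0)
clinical_d = ClinicalScalars(sbp=120, dbp=80, heart_rate=63, artery="cca", diameter=6.0)
params_d = estimate_wk3_noninvasive(clinical_d, law=law)
print(f"diameter route (D=6 mm): R1 = {params_d.r1:.3f}, R2 = {params_d.r2:.2f}, "
      f"C = {params_d.c:.4f}")
# These are ready to use as an outflow boundary condition in a 3-D CFD model.
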