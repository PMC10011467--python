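"""Forward WK3 simulation: carotid-template flow in, pressure waveform out.

Builds a carotid flow waveform (mean 7.63 mL/s, period 0.952 s), applies the
cohort-median carotid parameters, and prints the simulated pressure summary.
The mean pressure must equal Rtot x mean flow — the capacitor stores no net
charge over a cycle.
"""

import numpy as np

from windkessel3 import WK3Params, simulate_pressure, waveform_mean
from windkessel3.synthetic import DEFAULT_TEMPLATES, make_flow_template

flow = make_flow_template(DEFAULT_TEMPLATES["cca"]).to_waveform(mean=7.63, period=0.952)
params = WK3Params(r1=1.14, r2=10.35, c=0.04)

pressure = simulate_pressure(flow, params)

print(f"Rtot = {params.rtot:.2f} mmHg s/mL")
print(f"mean flow      = {waveform_mean(flow):.3f} mL/s")
print(f"mean pressure  = {waveform_mean(pressure):.2f} mmHg "
      f"(Rtot x Qbar = {params.rtot * waveform_mean(flow):.2f})")
print(f"systolic/diastolic = {pressure.value.max():.1f}/{pressure.value.min():.1f} mmHg")
# The printed mean pressure matches Rtot x Qbar to solver accuracy; the
# systolic-diastolic swing is set by R1 and the RC filtering of the pulse.
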