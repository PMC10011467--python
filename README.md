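# windkessel3

Three-element Windkessel (WK3 / RCR) modelling of the aortic-arch branch
arteries — common carotid (CCA), subclavian (SA) and vertebral (VA) — for
researchers who need patient-specific outflow boundary conditions for
computational hemodynamics when full invasive waveform measurements are not
available.

## The model

The WK3 lumped model places a proximal resistor R1 in series with a parallel
distal resistor R2 and capacitor C (pressure ↔ voltage, flow ↔ current).
With the capacitor pressure Pc as state,

    dPc/dt = (Q(t) − Pc/R2) / C,        P(t) = Pc(t) + R1·Q(t)

and at periodic steady state the total resistance obeys Rtot = R1 + R2 = P̄/Q̄.
Because Rtot is pinned by the measured means, only two parameters are free.
The package works with the dimensionless forms

    r1norm = R1/Rtot,   r2norm = 1 − r1norm,   cnorm = Rtot·C/T

which transfer across patients with different flows, pressures and heart
rates. The library provides:

* **waveforms** — single-period flow/pressure containers, CSV I/O, periodic
  cubic-spline interpolation, smoothing, normalization onto the uniform
  0.01 grid, ensemble averaging;
* **wk3** — forward (flow → pressure) and inverse (pressure → flow)
  simulation by fixed-step RK4 (default 10⁻⁴ s) to periodic steady state,
  in dimensional and dimensionless form, with the analytic input impedance
  Z(ω) = R1 + R2/(1 + iωR2C) as cross-check;
* **estimation** — constrained trust-region least-squares identification of
  (r1norm, cnorm) from paired waveforms, the L2 relative-error metric
  e = 100·√(Σ(P_sim − P_exp)²/ΣP_exp²), and cohort median/IQR summaries;
* **pipeline / assessment** — mean arterial pressure (SBP − DBP)/3 + DBP,
  Rtot = MAP/Q̄, the flow–diameter power law Q̄ = k·D^b, non-invasive
  parameter estimation from a shipped cohort table, and train/test
  assessment of cohort-median parameters;
* **sensitivity** — seeded uniform Monte Carlo mapping of the pressure-match
  cost over the (r1norm, cnorm) plane (default 1500 draws);
* **synthetic** — artery-specific synthetic patients with known ground
  truth, emulating the source cohort's flow/pressure/heart-rate statistics
  and waveform morphologies.

## Worked example

Estimate carotid WK3 parameters from routine clinic numbers only
(`examples/03_noninvasive_estimate.py`):

```python
from windkessel3 import ClinicalScalars, estimate_wk3_noninvasive

clinical = ClinicalScalars(sbp=120, dbp=80, heart_rate=63, artery="cca",
                           mean_flow=458 / 60)   # mL/min -> mL/s
params = estimate_wk3_noninvasive(clinical)
```

prints

```
MAP  = 93.33 mmHg
T    = 0.952 s
Rtot = 12.23 mmHg s/mL
R1 = 1.223  R2 = 11.00 mmHg s/mL   C = 0.0358 mL/mmHg
```

MAP comes from the cuff pressures, Rtot from MAP over mean flow, the period
from the heart rate, and the cohort-median normalized carotid parameters
(r1norm = 0.10, cnorm = 0.46) are rescaled to this patient. The resulting
R1, R2, C can be used directly as an RCR outflow boundary condition.

The other examples cover forward simulation (`01`), parameter
identification from paired waveforms (`02`), Monte Carlo sensitivity
(`04`), and train/test assessment of cohort medians (`05`). A thin CLI
wraps the same functions:

```sh
wk3 estimate --artery cca --sbp 120 --dbp 80 --hr 63 --mean-flow 458 --out est.json
wk3 synth --n-patients 5 --seed 1 --out cohort/
wk3 fit --flow cohort/cca000_flow.csv --pressure cohort/cca000_pressure.csv \
    --artery cca --out fit.json
```

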