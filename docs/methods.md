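# Methods

## Model and assumptions

The three-element Windkessel treats the vascular bed distal to an arch
branch as a proximal resistance R1 (mmHg·s/mL) in series with a parallel
distal resistance R2 and compliance C (mL/mmHg). The state equation in the
capacitor pressure Pc,

    dPc/dt = (Q(t) − Pc/R2)/C,       P = Pc + R1·Q,

assumes a periodic inflow, lumped (zero-dimensional) distal mechanics, and
no inertance — the four-element variant is deliberately out of scope because
inertance is poorly identifiable from single-site measurements. At periodic
steady state the capacitor passes no net charge per cycle, which forces the
mean-value identity P̄ = (R1 + R2)·Q̄; the package leans on this identity
both to constrain fits (Rtot is never a free parameter) and as a
conservation check of the solver.

The inverse direction integrates
R1·C·dQ/dt = C·dP/dt − Q·(1 + R1/R2) + P/R2, with dP/dt taken from the
periodic cubic spline of the pressure samples. It becomes stiff as R1 → 0;
the solver raises a descriptive error pointing at the algebraic limit
Q = C·dP/dt + P/R2 rather than silently producing garbage.

## Numerical scheme

Both directions use classical fixed-step RK4, default step 1e-4 s (never
more than T/100). For a linear constant-coefficient ODE one RK4 step is the
affine recurrence y_{k+1} = α·y_k + β_k with
α = 1 + z + z²/2 + z³/6 + z⁴/24, z = λh, and β_k a fixed combination of the
forcing at the step endpoints and midpoint. The per-cycle propagation is a
vectorised scan of that recurrence, chunked so inverse powers of α stay
below e⁶⁰ (no overflow for strongly damped steps); the result is
bit-identical to the sequential RK4 loop. Steps with α outside (0, 1] are
rejected as unstable with guidance to shrink the step.

Periodic steady state is declared when the max-norm relative change between
consecutive cycle traces falls below `cycle_tolerance` (default 1e-6,
`max_cycles` 50). Because the one-cycle map Pc(T) = A·Pc(0) + B is affine
with A = α^N known analytically, the solver jumps to the exact fixed point
B/(1 − A) after the first cycle and then verifies the cycle-to-cycle
criterion; convergence therefore takes three cycles regardless of how the
relaxation time R2·C compares with the period (plain iteration would need
thousands of cycles when R2·C ≫ T). The initial condition Pc(0) = R2·Q̄ is
the steady mean of the capacitor node. Halving the step changes the steady
trace by < 1e-6 relative (verified in tests), consistent with fourth-order
accuracy.

Flow and pressure between samples come from a periodic cubic spline
(`CubicSpline(..., bc_type="periodic")` with the wrap point appended), so
dQ/dt and dP/dt are analytic derivatives of the interpolant rather than
finite differences. A linear interpolant is available as a configurable
fallback.

## Waveform conventions

A waveform is one cardiac period: strictly increasing times spanning less
than T, at least 2 samples (16+ recommended for spectral accuracy of the
trapezoidal period mean), pressure strictly positive, flow free to reverse.
Internal flow units are mL/s; the CSV reader converts mL/min. The
dimensionless grid is half-open, {0, 0.01, …, 0.99} — 100 points, the
period endpoint excluded so it is not double counted. Normalization divides
values by the periodic-trapezoid mean and time by T, resamples onto the
grid, then rescales so the grid mean is exactly 1; this makes normalization
idempotent and the unit-mean invariant exact. Smoothing of multi-beat
pressure recordings phase-averages whole cycles at the heart-rate-derived
period and keeps the first 10 harmonics of the cardiac frequency
(zero-phase Fourier truncation; the DC term — the mean — is untouched).

## Parameter identification

`fit_wk3` fixes Rtot = P̄/Q̄ from the measured means and optimizes
x = (r1norm, log cnorm) with scipy's trust-region-reflective least squares,
bounds r1norm ∈ [1e-3, 0.999], cnorm ∈ [1e-3, 10], parameter and function
tolerances 0.001. The log scale for cnorm makes the search scale-free.
Residuals are evaluated on the 100-point normalized grid mapped to
dimensional time — the integration step governs solver accuracy, not the
residual sampling — and only on the converged steady-state cycle. The
initial guess is the artery's cohort median when the artery is known, else
(0.1, 0.5). Near-constant flow makes the Jacobian rank-deficient; such fits
return the initial guess flagged `identifiable=False` instead of crashing.
`cost_history` records the best-so-far SSE per residual evaluation, i.e.
the accepted-step history (scipy exposes no per-iteration callback; trf
only moves on improvement). Cohort summaries use linear-interpolation
(type-7) quantiles.

On noiseless synthetic patients of all three artery templates the recovered
(r1norm, cnorm) agree with the generating values to well below 0.5%; with
1 mmHg additive pressure noise the medians over 20 seeds stay within 5%
(both asserted in the test suite).

## Non-invasive pipeline

MAP = (SBP − DBP)/3 + DBP assumes systole occupies one third of the cycle;
T = 60/HR; Rtot = MAP/Q̄ with Q̄ measured or obtained from the power law
Q̄ = k·D^b. The power-law coefficients are study-specific and therefore a
required user input — no default k ships; exponents outside the reported
1.6–2.4 range for arch branches warn but do not fail. The shipped
normalized-parameter table holds the ten-patient cohort medians and IQRs
per artery; its provenance string records that vertebral entries were
identified against subclavian pressures and right-side arteries reused
left-side pressures (metadata only, no behavioural effect).

## Monte Carlo sensitivity

1500 (configurable) parameter pairs are drawn uniformly over
r1norm ∈ (0.001, 0.6], cnorm ∈ (0.01, 3.0] — ranges chosen to cover the
physiologically plausible basin, fully configurable — from one seeded
generator whose seed is recorded in the map. All draws are evaluated
exhaustively; the cost is the dimensionless SSE of the normalized simulated
pressure against the reference over the 0.01 grid, so absolute cost levels
are comparable only within a map. Gridding uses nearest-sample
interpolation on range-rescaled axes; the grid cell nearest the best sample
carries that sample's exact cost, so the surface minimum always equals the
sample minimum.

## Synthetic cohort

The generator defines the study conditions for every end-to-end check.
Per-artery defaults: mean flows lognormal moment-matched to 458 ± 139 (CCA),
185 ± 116 (SA), 90 ± 59 (VA) mL/min; mean pressures normal 83 ± 11 (CCA)
and 85 ± 12 mmHg (SA, reused for VA since no vertebral pressures were
measured); heart rate normal 63 ± 10 bpm; 10 patients per artery.
Normalized parameters are drawn lognormally around the cohort medians with
sigma matched to the published IQRs (σ = ln(q75/q25)/(2·0.6745)); draws
outside physical bounds (r1norm ≥ 0.8, cnorm > 8, non-positive scalars)
are redrawn with a bounded retry budget. Flow templates are truncated
Fourier series (12 harmonics) shaped by a systolic peak ratio (2.0 CCA,
4.0 SA, 1.7 VA), a subclavian early-diastolic reversal depth (−0.5), and a
1/3 systolic fraction, with an 8% lognormal shape jitter per patient;
amplitudes are iterated so peak and dip land on target after truncation.
These choices reproduce the morphology classes — mono-phasic carotid and
vertebral, sharp-peaked subclavian with reversal — not any specific
measured curve. Pressure is the exact forward simulation of the drawn
parameters plus Gaussian noise (default σ = 1 mmHg); cuff SBP/DBP are the
extrema of the noiseless simulated pressure, so MAP from the cuff formula
deliberately differs from the true waveform mean, as it does in practice.

What passing on synthetic data does *not* show: real test flows are not
generated by a WK3 model, so real pressure-direction errors include model
form error absent here (our synthetic pressure-direction medians, a few
percent, sit below the double-digit values seen on real recordings); beat-
to-beat variability, measurement phase errors and pathological morphologies
(e.g. subclavian steal) are not emulated. The qualitative conclusion that
does transfer — and is asserted end-to-end — is the direction asymmetry:
applying cohort-median parameters to unseen patients matches pressure far
better than flow, worst for the subclavian template whose waveform carries
the most high-frequency content.

## Problem sizes and determinism

Default test/acceptance sizes: cohorts of 10 patients per artery (the
source cohort's size), 20 noise seeds for recovery robustness, 1500 Monte
Carlo draws, RK4 step 1e-4 s. All randomness flows through
`numpy.random.default_rng` seeded explicitly; `scripts/acceptance.py`
derives independent stage seeds from its single `--seed` via
`SeedSequence`. Identical seeds give byte-identical cohorts and maps.

## Known limitations

Single-period, periodic-steady-state analysis only — no beat detection
beyond heart-rate-based cycle extraction, no arrhythmia. The inverse
direction degrades for small R1 (stiffness) and amplifies interpolation
noise in dP/dt. The fit is single-start; the cost surface is smooth and
single-basin for WK3-generated data but multi-start may help on noisy real
recordings. Fixed-step RK4 wastes work for very smooth cases and cannot
integrate the C → 0 limit without a smaller step.
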