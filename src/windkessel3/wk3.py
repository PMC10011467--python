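"""Three-element Windkessel (RCR) model: forward and inverse simulation.

The model is a proximal resistor ``R1`` in series with a parallel
combination of a distal resistor ``R2`` and a capacitor ``C`` (pressure ↔
voltage, flow ↔ current).  With the capacitor pressure ``Pc`` as the state,

    dPc/dt = (Q(t) - Pc/R2) / C,        P(t) = Pc(t) + R1 * Q(t)

maps flow to pressure.  The inverse direction (pressure to flow) integrates

    R1*C * dQ/dt = C * dP/dt - Q * (1 + R1/R2) + P/R2,

with dP/dt taken from the periodic spline of the pressure samples.

Both directions are integrated with classical fixed-step RK4 (default step
1e-4 s) to the periodic steady state: cycles are repeated until the max-norm
relative change of the trace between consecutive cycles drops below the
cycle tolerance.  Because the ODE is linear with constant coefficients, one
RK4 step is the affine recurrence ``y_{k+1} = alpha*y_k + beta_k`` with a
constant ``alpha``; the solver exploits this twice:

* each cycle is propagated by a vectorised scan (chunked so powers of
  ``alpha`` never overflow) — bit-identical to the plain RK4 loop;
* after the first cycle the exact periodic fixed point of the affine
  one-cycle map ``Pc(T) = A*Pc(0) + B`` is used as the next initial
  condition, so convergence is reached in three cycles even when the
  relaxation time ``R2*C`` far exceeds the period.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .waveforms import GRID, NormalizedWaveform, Waveform, waveform_mean

__all__ = [
    "WK3Params",
    "SolverSettings",
    "ConvergenceError",
    "StiffnessError",
    "simulate_pressure",
    "estimate_flow",
    "simulate_pressure_normalized",
    "PressureSimulator",
    "NormalizedPressureSimulator",
    "input_impedance",
]


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached within ``max_cycles``."""

    def __init__(self, message: str, residual: float) -> None:
        super().__init__(message)
        self.residual = residual


class StiffnessError(RuntimeError):
    """The fixed RK4 step is unstable for the requested parameters."""


@dataclass(frozen=True)
class WK3Params:
    """WK3 parameters: R1, R2 in mmHg·s/mL, C in mL/mmHg (all positive)."""

    r1: float
    r2: float
    c: float

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0 and self.c > 0):
            raise ValueError(f"R1, R2, C must all be positive, got {self}")

    @property
    def rtot(self) -> float:
        """Total resistance R1 + R2, mmHg·s/mL."""
        return self.r1 + self.r2


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-step RK4 settings.

    step : time step in seconds (default 1e-4); capped at period/100.
    max_cycles : maximum cardiac cycles before giving up.
    cycle_tolerance : max-norm relative change between consecutive cycles
        below which the solution is declared periodic.
    """

    step: float = 1e-4
    max_cycles: int = 50
    cycle_tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.max_cycles < 2:
            raise ValueError("max_cycles must be at least 2")
        if self.cycle_tolerance <= 0:
            raise ValueError("cycle_tolerance must be positive")

    def n_steps(self, period: float) -> int:
        """Steps per cycle; at least 100 so the step never exceeds T/100."""
        return max(100, int(round(period / self.step)))


def _rk4_affine_coeffs(z: float) -> tuple[float, float, float]:
    """RK4 per-step coefficients for y' = lam*y + g(t), z = lam*h.

    Returns (alpha, c0, cm) such that
    ``y_{k+1} = alpha*y_k + (h/6)*(c0*g_k + cm*g_{k+1/2} + g_{k+1})``.
    """
    alpha = 1.0 + z * (1.0 + z * (0.5 + z * (1.0 / 6.0 + z / 24.0)))
    c0 = 1.0 + z * (1.0 + z * (0.5 + z * 0.25))
    cm = 4.0 + z * (2.0 + z * 0.5)
    return alpha, c0, cm


def _propagate(y0: float, alpha: float, beta: np.ndarray) -> np.ndarray:
    """Scan the affine recurrence y_{k+1} = alpha*y_k + beta_k, k = 0..n-1.

    Vectorised in chunks sized so that ``alpha**(-m)`` stays below ~e^60,
    avoiding overflow for strongly damped steps.  Identical (to roundoff) to
    the sequential loop.
    """
    n = beta.size
    y = np.empty(n + 1)
    y[0] = y0
    if alpha == 1.0:
        y[1:] = y0 + np.cumsum(beta)
        return y
    la = -np.log(alpha)  # > 0 for 0 < alpha < 1
    m = n if la * n < 60.0 else max(1, int(60.0 / la))
    cur = y0
    pos = 0
    while pos < n:
        mm = min(m, n - pos)
        k = np.arange(1, mm + 1)
        powers = np.exp(-la * k)  # alpha**k
        s = np.cumsum(beta[pos:pos + mm] * np.exp(la * k))  # beta_j * alpha**-(j+1)
        y[pos + 1:pos + 1 + mm] = powers * (cur + s)
        cur = y[pos + mm]
        pos += mm
    return y


def _steady_cycle(lam: float, g_half: np.ndarray, h: float, n: int, y0: float,
                  settings: SolverSettings) -> np.ndarray:
    """Periodic steady-state trace of y' = lam*y + g(t) over one cycle.

    ``g_half`` holds g at the 2n+1 half-step points t0, t0+h/2, ..., t0+n*h.
    Returns the state at the n+1 step points of the converged cycle.
    """
    z = lam * h
    alpha, c0, cm = _rk4_affine_coeffs(z)
    if not (0.0 < alpha <= 1.0):
        raise StiffnessError(
            f"RK4 unstable at step {h:.3g} s for decay rate {lam:.3g} 1/s "
            f"(alpha = {alpha:.3g}); reduce the solver step")
    g0 = g_half[0:2 * n:2]
    gm = g_half[1:2 * n:2]
    g1 = g_half[2::2]
    beta = (h / 6.0) * (c0 * g0 + cm * gm + g1)
    big_a = np.exp(n * np.log(alpha)) if alpha < 1.0 else 1.0

    prev = None
    y = float(y0)
    residual = np.inf
    for cycle in range(settings.max_cycles):
        trace = _propagate(y, alpha, beta)
        if prev is not None:
            scale = float(np.max(np.abs(trace))) or 1.0
            residual = float(np.max(np.abs(trace - prev))) / scale
            if residual < settings.cycle_tolerance:
                return trace
        if cycle == 0 and big_a < 1.0:
            # affine one-cycle map: trace[-1] = A*y + B; jump to its fixed point
            y = (trace[-1] - big_a * y) / (1.0 - big_a)
        else:
            y = float(trace[-1])
        prev = trace
    raise ConvergenceError(
        f"no periodic steady state within {settings.max_cycles} cycles "
        f"(last cycle-to-cycle residual {residual:.3g})", residual)


class PressureSimulator:
    """Forward WK3 simulations (flow → pressure) for one fixed flow waveform.

    Precomputes the fine-grid flow samples once so repeated simulations with
    different parameters (inside an optimizer or Monte Carlo loop) are cheap.
    """

    def __init__(self, flow: Waveform, settings: SolverSettings | None = None) -> None:
        self.flow = flow
        self.settings = settings or SolverSettings()
        T = flow.period
        self.n = self.settings.n_steps(T)
        self.h = T / self.n
        sp = flow.interpolant()
        t0 = float(flow.time[0])
        self.t_fine = t0 + np.arange(self.n + 1) * self.h
        t_half = t0 + np.arange(2 * self.n + 1) * (self.h / 2.0)
        self.q_half = np.asarray(sp(t_half), dtype=float)
        self.qbar = waveform_mean(flow)

    def run(self, params: WK3Params) -> np.ndarray:
        """Steady-state pressure sampled on the flow waveform's time base."""
        lam = -1.0 / (params.r2 * params.c)
        g = self.q_half / params.c
        trace = _steady_cycle(lam, g, self.h, self.n, params.r2 * self.qbar,
                              self.settings)
        pc = np.interp(self.flow.time, self.t_fine, trace)
        return pc + params.r1 * self.flow.value


def simulate_pressure(flow: Waveform, params: WK3Params,
                      settings: SolverSettings | None = None) -> Waveform:
    """Simulate the periodic steady-state pressure from a flow waveform.

    Returns the pressure on the flow waveform's time base.
    """
    sim = PressureSimulator(flow, settings)
    return Waveform(time=flow.time, value=sim.run(params),
                    period=flow.period, quantity="pressure")


def estimate_flow(pressure: Waveform, params: WK3Params,
                  settings: SolverSettings | None = None) -> Waveform:
    """Estimate the flow waveform that produces a given pressure (inverse WK3).

    Integrates ``R1*C*dQ/dt = C*dP/dt - Q*(1 + R1/R2) + P/R2`` to periodic
    steady state; dP/dt comes from the periodic spline of the samples.
    Small R1 makes this direction stiff; if the fixed step is unstable a
    :class:`StiffnessError` explains the algebraic fallback
    ``Q = C*dP/dt + P/R2`` that applies in the R1 → 0 limit.
    """
    settings = settings or SolverSettings()
    T = pressure.period
    n = settings.n_steps(T)
    h = T / n
    sp = pressure.interpolant()
    t0 = float(pressure.time[0])
    t_half = t0 + np.arange(2 * n + 1) * (h / 2.0)
    p_half = np.asarray(sp(t_half), dtype=float)
    dp_half = np.asarray(sp.derivative(t_half), dtype=float)
    lam = -(1.0 + params.r1 / params.r2) / (params.r1 * params.c)
    g = dp_half / params.r1 + p_half / (params.r1 * params.r2 * params.c)
    pbar = waveform_mean(pressure)
    try:
        trace = _steady_cycle(lam, g, h, n, pbar / params.rtot, settings)
    except StiffnessError as err:
        raise StiffnessError(
            f"{err}; the inverse direction is stiff for small R1 — in the "
            "R1=0 limit use the algebraic relation Q = C*dP/dt + P/R2") from err
    t_fine = t0 + np.arange(n + 1) * h
    q = np.interp(pressure.time, t_fine, trace)
    return Waveform(time=pressure.time, value=q, period=T, quantity="flow")


class NormalizedPressureSimulator:
    """Forward simulations in the dimensionless system (Rtot = 1, T = 1).

    State equation: ``dPc/dtau = (q - Pc/r2norm) / cnorm``, output
    ``p = Pc + r1norm*q``; the governing equation has the same form as the
    dimensional one, which is what makes normalized parameters transferable.
    """

    def __init__(self, flow_norm: NormalizedWaveform,
                 settings: SolverSettings | None = None) -> None:
        self.flow_norm = flow_norm
        self.settings = settings or SolverSettings()
        self.n = self.settings.n_steps(1.0)
        self.h = 1.0 / self.n
        sp = flow_norm.interpolant()
        self.t_fine = np.arange(self.n + 1) * self.h
        t_half = np.arange(2 * self.n + 1) * (self.h / 2.0)
        self.q_half = np.asarray(sp(t_half), dtype=float)

    def run(self, r1norm: float, cnorm: float) -> np.ndarray:
        """Normalized steady-state pressure on the 0.01 grid (mean exactly 1)."""
        r2norm = 1.0 - r1norm
        if not (0.0 < r1norm < 1.0 and cnorm > 0.0):
            raise ValueError(f"need 0 < r1norm < 1 and cnorm > 0, got ({r1norm}, {cnorm})")
        lam = -1.0 / (r2norm * cnorm)
        g = self.q_half / cnorm
        trace = _steady_cycle(lam, g, self.h, self.n, r2norm, self.settings)
        pc = np.interp(GRID, self.t_fine, trace)
        p = pc + r1norm * self.flow_norm.value
        return p / p.mean()


def simulate_pressure_normalized(flow_norm: NormalizedWaveform, nparams,
                                 settings: SolverSettings | None = None) -> NormalizedWaveform:
    """Normalized forward simulation; ``nparams`` needs r1norm and cnorm."""
    sim = NormalizedPressureSimulator(flow_norm, settings)
    value = sim.run(float(nparams.r1norm), float(nparams.cnorm))
    return NormalizedWaveform(value=value, quantity="pressure")


def input_impedance(params: WK3Params, omega) -> np.ndarray:
    """Analytic WK3 input impedance Z(ω) = R1 + R2 / (1 + iωR2C).

    ``omega`` in rad/s; returns a complex array.  This closed form is the
    frequency-domain description of the same circuit the time-domain solver
    integrates, and serves as its independent oracle for sinusoidal forcing.
    """
    omega = np.asarray(omega, dtype=float)
    return params.r1 + params.r2 / (1.0 + 1j * omega * params.r2 * params.c)
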