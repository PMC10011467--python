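"""Identification of patient-specific WK3 parameters from paired waveforms.

Because the total resistance is pinned by the measured means,
``Rtot = P̄/Q̄``, only two parameters are free.  The fit optimizes the
dimensionless pair ``(r1norm, cnorm)`` — with ``cnorm`` on a log scale so
the search is scale-free — by bounded trust-region-reflective nonlinear
least squares on the pressure residuals ``P_simul(t_k) − P_exp(t_k)``.  The
residual grid is the 100-point normalized grid mapped to dimensional time;
the integration step of the solver is independent of the residual sampling.

The waveform-matching quality is the L2 relative error (in percent)

    e_L2 = 100 * sqrt( Σ (P_simul − P_exp)² / Σ P_exp² ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pipeline import (NormalizedParameterTable, NormalizedWK3Params,
                       ParameterQuantiles, default_table, denormalize_params,
                       normalize_params)
from .waveforms import GRID, NormalizedWaveform, Waveform, waveform_mean
from .wk3 import PressureSimulator, SolverSettings, WK3Params

__all__ = [
    "FitSettings",
    "FitResult",
    "PatientRecord",
    "CohortFit",
    "fit_wk3",
    "l2_relative_error",
    "fit_cohort",
]


@dataclass(frozen=True)
class FitSettings:
    """Optimizer settings for the two-parameter WK3 fit.

    parameter_tolerance / function_tolerance : relative step / cost
        tolerances of the trust-region solver (default 0.001 each).
    r1norm_bounds, cnorm_bounds : box constraints on the free parameters.
    initial_guess : optional (r1norm, cnorm) start; defaults to the
        artery-specific cohort medians when the artery is known, else
        (0.1, 0.5).
    max_iterations : cap on residual evaluations.
    """

    parameter_tolerance: float = 1e-3
    function_tolerance: float = 1e-3
    r1norm_bounds: tuple[float, float] = (1e-3, 0.999)
    cnorm_bounds: tuple[float, float] = (1e-3, 10.0)
    initial_guess: tuple[float, float] | None = None
    max_iterations: int = 200

    def __post_init__(self) -> None:
        if self.parameter_tolerance <= 0 or self.function_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        for lo, hi in (self.r1norm_bounds, self.cnorm_bounds):
            if not (0 < lo < hi):
                raise ValueError("bounds must satisfy 0 < lo < hi")
        if self.initial_guess is not None:
            r1n, cn = self.initial_guess
            if not (self.r1norm_bounds[0] <= r1n <= self.r1norm_bounds[1]
                    and self.cnorm_bounds[0] <= cn <= self.cnorm_bounds[1]):
                raise ValueError("initial guess outside bounds")


@dataclass(frozen=True)
class FitResult:
    """Identified parameters plus goodness-of-fit diagnostics.

    ``sse`` is the sum of squared pressure error (mmHg²) over the comparison
    grid; ``cost_history`` is the accepted (best-so-far) SSE per residual
    evaluation; ``identifiable`` is False for degenerate inputs (e.g.
    constant flow) whose Jacobian is rank-deficient.
    """

    params: WK3Params
    normalized: NormalizedWK3Params
    sse: float
    l2_error_percent: float
    iterations: int
    converged: bool
    cost_history: np.ndarray
    identifiable: bool = True


def l2_relative_error(simulated, expected) -> float:
    """L2-norm relative error between two traces on the same grid, percent.

    Accepts :class:`Waveform` / :class:`NormalizedWaveform` pairs (which must
    share their sampling grid) or plain arrays of equal length.
    """
    def _values(obj):
        if isinstance(obj, Waveform):
            return obj.value, obj.time
        if isinstance(obj, NormalizedWaveform):
            return obj.value, obj.grid
        return np.asarray(obj, dtype=float), None

    sim, tg_sim = _values(simulated)
    exp, tg_exp = _values(expected)
    if sim.shape != exp.shape:
        raise ValueError(f"grid mismatch: {sim.shape} vs {exp.shape}")
    if tg_sim is not None and tg_exp is not None and not np.allclose(tg_sim, tg_exp):
        raise ValueError("waveforms are sampled on different time grids")
    denom = float(np.sum(exp ** 2))
    if denom == 0.0:
        raise ValueError("expected trace has zero norm")
    return 100.0 * float(np.sqrt(np.sum((sim - exp) ** 2) / denom))


def _comparison_grid(flow: Waveform, pressure: Waveform) -> tuple[Waveform, np.ndarray, float]:
    """Resample both waveforms onto the 100-point grid in dimensional time."""
    if abs(flow.period - pressure.period) > 1e-6 * flow.period:
        raise ValueError(
            f"flow and pressure periods differ: {flow.period} vs {pressure.period}")
    T = flow.period
    t_grid = GRID * T
    q = np.asarray(flow.interpolant()(t_grid), dtype=float)
    p = np.asarray(pressure.interpolant()(t_grid), dtype=float)
    flow_grid = Waveform(time=t_grid, value=q, period=T, quantity="flow")
    return flow_grid, p, T


def fit_wk3(flow: Waveform, pressure_measured: Waveform,
            settings: FitSettings | None = None,
            solver: SolverSettings | None = None,
            artery: str | None = None,
            table: NormalizedParameterTable | None = None) -> FitResult:
    """Identify WK3 parameters from one paired flow/pressure measurement.

    ``Rtot`` is fixed at the ratio of measured means, so the returned
    parameters satisfy ``R1 + R2 = P̄/Q̄`` exactly; only ``(r1norm, cnorm)``
    are optimized.  When ``artery`` is given the initial guess defaults to
    that artery's cohort medians.
    """
    settings = settings or FitSettings()
    solver = solver or SolverSettings()
    qbar = waveform_mean(flow)
    pbar = waveform_mean(pressure_measured)
    if qbar <= 0 or pbar <= 0:
        raise ValueError(f"mean flow and mean pressure must be positive "
                         f"(got Q̄={qbar:.4g}, P̄={pbar:.4g})")
    rtot = pbar / qbar

    flow_grid, p_exp, T = _comparison_grid(flow, pressure_measured)
    sim = PressureSimulator(flow_grid, solver)

    if settings.initial_guess is not None:
        x0_params = settings.initial_guess
    elif artery is not None:
        med = (table or default_table()).median_params(artery)
        x0_params = (med.r1norm, med.cnorm)
    else:
        x0_params = (0.1, 0.5)

    # degenerate (near-constant) flow: the residual does not depend on the
    # parameters, the Jacobian is rank-deficient — return the initial guess.
    q = flow_grid.value
    identifiable = float(np.std(q)) > 1e-9 * abs(qbar)

    history: list[float] = []

    def residual(x: np.ndarray) -> np.ndarray:
        nparams = NormalizedWK3Params(r1norm=float(x[0]), cnorm=float(np.exp(x[1])))
        params = denormalize_params(nparams, rtot, T)
        r = sim.run(params) - p_exp
        history.append(float(np.sum(r ** 2)))
        return r

    x0 = np.array([x0_params[0], np.log(x0_params[1])])
    if not identifiable:
        r0 = residual(x0)
        nparams = NormalizedWK3Params(r1norm=x0_params[0], cnorm=x0_params[1])
        params = denormalize_params(nparams, rtot, T)
        return FitResult(params=params, normalized=nparams,
                         sse=float(np.sum(r0 ** 2)),
                         l2_error_percent=l2_relative_error(sim.run(params), p_exp),
                         iterations=1, converged=True,
                         cost_history=np.asarray(history), identifiable=False)

    lo = np.array([settings.r1norm_bounds[0], np.log(settings.cnorm_bounds[0])])
    hi = np.array([settings.r1norm_bounds[1], np.log(settings.cnorm_bounds[1])])
    res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                        xtol=settings.parameter_tolerance,
                        ftol=settings.function_tolerance,
                        gtol=1e-12, max_nfev=settings.max_iterations)
    nparams = NormalizedWK3Params(r1norm=float(res.x[0]), cnorm=float(np.exp(res.x[1])))
    params = denormalize_params(nparams, rtot, T)
    p_opt = sim.run(params)
    return FitResult(params=params, normalized=nparams,
                     sse=float(np.sum((p_opt - p_exp) ** 2)),
                     l2_error_percent=l2_relative_error(p_opt, p_exp),
                     iterations=int(res.nfev), converged=bool(res.success),
                     cost_history=np.minimum.accumulate(np.asarray(history)),
                     identifiable=True)


@dataclass(frozen=True)
class PatientRecord:
    """One artery of one patient: paired flow and pressure waveforms."""

    patient_id: str
    artery: str
    flow: Waveform
    pressure: Waveform


@dataclass(frozen=True)
class CohortFit:
    """Per-patient fits plus per-artery parameter summaries.

    ``fits`` maps (patient_id, artery) to a :class:`FitResult` or, for
    patients whose fit failed, to the error message (failures are flagged,
    never raised, so one bad patient cannot abort a cohort).
    ``summary`` holds median/q25/q75 of the normalized and non-normalized
    parameters per artery (linear-interpolation quantiles).
    """

    fits: dict
    summary: pd.DataFrame

    def to_table(self, provenance: str = "fitted cohort") -> NormalizedParameterTable:
        """Build a normalized-parameter table from the per-artery summaries."""
        entries = {}
        for artery, row in self.summary.iterrows():
            entries[artery] = {
                "r1norm": ParameterQuantiles(row["r1norm_median"], row["r1norm_q25"],
                                             row["r1norm_q75"]),
                "cnorm": ParameterQuantiles(row["cnorm_median"], row["cnorm_q25"],
                                            row["cnorm_q75"]),
            }
        return NormalizedParameterTable(entries=entries, provenance=provenance)


def fit_cohort(patients: Sequence[PatientRecord],
               settings: FitSettings | None = None,
               solver: SolverSettings | None = None,
               table: NormalizedParameterTable | None = None) -> CohortFit:
    """Fit every patient and summarize parameters per artery.

    Quantiles use numpy's default linear interpolation (type 7).
    """
    if not patients:
        raise ValueError("empty cohort")
    fits: dict = {}
    rows: dict[str, list] = {}
    for rec in patients:
        try:
            fr = fit_wk3(rec.flow, rec.pressure, settings=settings, solver=solver,
                         artery=rec.artery, table=table)
        except Exception as err:  # flagged, not fatal
            fits[(rec.patient_id, rec.artery)] = f"fit failed: {err}"
            continue
        fits[(rec.patient_id, rec.artery)] = fr
        rows.setdefault(rec.artery, []).append(fr)

    summary_rows = []
    for artery, results in sorted(rows.items()):
        entry = {"artery": artery, "n": len(results)}
        for name, get in (
            ("r1norm", lambda f: f.normalized.r1norm),
            ("r2norm", lambda f: f.normalized.r2norm),
            ("cnorm", lambda f: f.normalized.cnorm),
            ("r1", lambda f: f.params.r1),
            ("r2", lambda f: f.params.r2),
            ("c", lambda f: f.params.c),
        ):
            vals = np.array([get(f) for f in results])
            entry[f"{name}_median"] = float(np.median(vals))
            entry[f"{name}_q25"] = float(np.percentile(vals, 25))
            entry[f"{name}_q75"] = float(np.percentile(vals, 75))
        summary_rows.append(entry)
    summary = pd.DataFrame(summary_rows).set_index("artery") if summary_rows \
        else pd.DataFrame()
    return CohortFit(fits=fits, summary=summary)
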