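"""Train/test assessment of cohort-derived normalized WK3 parameters.

The training cohort is fitted per patient; the per-artery medians of the
normalized parameters are then rescaled to each testing patient's own
``Rtot`` (from its measured means) and period, and the resulting WK3 model
is exercised in both directions:

* pressure direction — measured flow in, simulated pressure out, compared
  with the measured pressure;
* flow direction — measured pressure in, estimated flow out, compared with
  the measured flow.

Errors are the L2 relative error (percent) on the 100-point normalized grid
in dimensional time, summarized as median (IQR) per artery.  The pressure
direction is expected to tolerate parameter mismatch far better than the
flow direction: pressure is a low-pass response of the circuit, while the
inverse direction amplifies the high-frequency waveform content that a
three-element model cannot carry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import (FitSettings, PatientRecord, _comparison_grid,
                         fit_cohort, l2_relative_error)
from .pipeline import NormalizedParameterTable, denormalize_params
from .waveforms import GRID, waveform_mean
from .wk3 import SolverSettings, estimate_flow, simulate_pressure

__all__ = ["AssessmentReport", "evaluate_on_testset"]


@dataclass(frozen=True)
class AssessmentReport:
    """Outcome of :func:`evaluate_on_testset`.

    table : normalized-parameter table derived from the training cohort.
    per_patient : one row per testing record with both direction errors
        (rows whose evaluation failed carry the error message in ``flag``).
    summary : per-artery median/q25/q75 of both error directions, percent.
    """

    table: NormalizedParameterTable
    per_patient: pd.DataFrame
    summary: pd.DataFrame


def evaluate_on_testset(training: Sequence[PatientRecord],
                        testing: Sequence[PatientRecord],
                        settings: FitSettings | None = None,
                        solver: SolverSettings | None = None) -> AssessmentReport:
    """Assess training-cohort median parameters on an independent test set."""
    if not training or not testing:
        raise ValueError("training and testing cohorts must both be nonempty")
    cohort = fit_cohort(training, settings=settings, solver=solver)
    table = cohort.to_table(provenance="training-cohort medians")

    rows = []
    for rec in testing:
        row = {"patient_id": rec.patient_id, "artery": rec.artery,
               "pressure_error_pct": np.nan, "flow_error_pct": np.nan, "flag": ""}
        try:
            qbar = waveform_mean(rec.flow)
            pbar = waveform_mean(rec.pressure)
            rtot = pbar / qbar
            T = rec.flow.period
            params = denormalize_params(table.median_params(rec.artery), rtot, T)
            flow_grid, p_exp, _ = _comparison_grid(rec.flow, rec.pressure)
            p_sim = simulate_pressure(flow_grid, params, solver)
            row["pressure_error_pct"] = l2_relative_error(p_sim.value, p_exp)
            t_grid = GRID * T
            pressure_grid = rec.pressure.interpolant()(t_grid)
            from .waveforms import Waveform
            pw = Waveform(time=t_grid, value=pressure_grid, period=T,
                          quantity="pressure")
            q_sim = estimate_flow(pw, params, solver)
            row["flow_error_pct"] = l2_relative_error(q_sim.value, flow_grid.value)
        except Exception as err:  # flagged, not fatal
            row["flag"] = str(err)
        rows.append(row)
    per_patient = pd.DataFrame(rows)

    summary_rows = []
    for artery, grp in per_patient.groupby("artery"):
        entry = {"artery": artery, "n": int(len(grp))}
        for col in ("pressure_error_pct", "flow_error_pct"):
            vals = grp[col].dropna().to_numpy()
            if vals.size:
                entry[f"{col}_median"] = float(np.median(vals))
                entry[f"{col}_q25"] = float(np.percentile(vals, 25))
                entry[f"{col}_q75"] = float(np.percentile(vals, 75))
        summary_rows.append(entry)
    summary = pd.DataFrame(summary_rows).set_index("artery")
    return AssessmentReport(table=table, per_patient=per_patient, summary=summary)
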