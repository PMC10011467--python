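"""Normalization pipeline: clinical scalars → patient-specific WK3 parameters.

Parameters fitted from paired flow/pressure waveforms are made dimensionless

    r1norm = R1/Rtot,   r2norm = R2/Rtot = 1 - r1norm,   cnorm = Rtot*C/T

so they transfer across patients with different flows, pressures and heart
rates.  The non-invasive estimation path inverts this: brachial cuff
pressures give the mean arterial pressure (MAP), mean flow (measured, or
from a flow–diameter power law) gives the total resistance Rtot = P̄/Q̄,
heart rate gives the period T = 60/HR, and cohort-median normalized
parameters are rescaled to the patient:

    R1 = r1norm*Rtot,   R2 = r2norm*Rtot,   C = cnorm*T/Rtot.

The shipped default cohort table holds the artery-specific medians and
interquartile ranges for common carotid (CCA), subclavian (SA) and vertebral
(VA) arteries derived from a ten-patient thoracic-endovascular-repair
cohort.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .wk3 import WK3Params

__all__ = [
    "ARTERIES",
    "NormalizedWK3Params",
    "ClinicalScalars",
    "NormalizedParameterTable",
    "FlowDiameterLaw",
    "default_table",
    "mean_arterial_pressure",
    "total_resistance",
    "normalize_params",
    "denormalize_params",
    "mean_flow_from_diameter",
    "estimate_wk3_noninvasive",
]

#: Supported arch-branch arteries: common carotid, subclavian, vertebral.
ARTERIES = ("cca", "sa", "va")


@dataclass(frozen=True)
class NormalizedWK3Params:
    """Dimensionless WK3 parameters; r2norm = 1 - r1norm is derived."""

    r1norm: float
    cnorm: float

    def __post_init__(self) -> None:
        if not (0.0 < self.r1norm < 1.0):
            raise ValueError(f"r1norm must lie in (0, 1), got {self.r1norm}")
        if not self.cnorm > 0.0:
            raise ValueError(f"cnorm must be positive, got {self.cnorm}")

    @property
    def r2norm(self) -> float:
        return 1.0 - self.r1norm


@dataclass(frozen=True)
class ClinicalScalars:
    """Non-invasive clinical inputs for one artery of one patient.

    sbp, dbp : brachial cuff systolic/diastolic pressure, mmHg.
    heart_rate : beats per minute (period T = 60/heart_rate seconds).
    mean_flow : mean flow in mL/s (optional if a diameter + law is given).
    diameter : lumen diameter in mm (optional if mean_flow is given).
    artery : one of {"cca", "sa", "va"}.
    """

    sbp: float
    dbp: float
    heart_rate: float
    artery: str
    mean_flow: float | None = None
    diameter: float | None = None

    def __post_init__(self) -> None:
        if not (self.sbp > self.dbp > 0):
            raise ValueError(f"need sbp > dbp > 0, got sbp={self.sbp}, dbp={self.dbp}")
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if self.artery not in ARTERIES:
            raise ValueError(f"artery must be one of {ARTERIES}, got {self.artery!r}")
        if self.mean_flow is None and self.diameter is None:
            raise ValueError("at least one of mean_flow or diameter is required")

    @property
    def period(self) -> float:
        """Cardiac period T = 60/heart_rate, seconds."""
        return 60.0 / self.heart_rate


@dataclass(frozen=True)
class ParameterQuantiles:
    """Median and 25th/75th percentiles of one dimensionless parameter."""

    median: float
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if not (self.q25 <= self.median <= self.q75):
            raise ValueError(
                f"median must lie within its IQR, got {self.median} vs ({self.q25}, {self.q75})")


@dataclass(frozen=True)
class NormalizedParameterTable:
    """Per-artery median and IQR of (r1norm, cnorm); r2norm is derived."""

    entries: Mapping[str, Mapping[str, ParameterQuantiles]]
    provenance: str = ""

    def median_params(self, artery: str) -> NormalizedWK3Params:
        if artery not in self.entries:
            raise KeyError(f"artery {artery!r} not present in table "
                           f"(available: {sorted(self.entries)})")
        e = self.entries[artery]
        return NormalizedWK3Params(r1norm=e["r1norm"].median, cnorm=e["cnorm"].median)

    def to_json(self, path=None) -> str:
        payload = {
            artery: {name: vars(q) for name, q in entry.items()}
            for artery, entry in self.entries.items()
        }
        payload["provenance"] = self.provenance
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NormalizedParameterTable":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        provenance = payload.pop("provenance", "")
        entries = {
            artery: {name: ParameterQuantiles(**q) for name, q in entry.items()}
            for artery, entry in payload.items()
        }
        return cls(entries=entries, provenance=provenance)


def default_table() -> NormalizedParameterTable:
    """Cohort-median normalized parameters shipped with the package.

    Medians (IQR) from a ten-patient TEVAR cohort, by artery.  Vertebral
    fits used subclavian pressure waveforms (intra-operative vertebral
    pressure measurement being too risky), and right-side arteries reused
    left-side pressures; both facts are recorded as provenance only.
    """
    entries = {
        "cca": {
            "r1norm": ParameterQuantiles(0.10, 0.07, 0.15),
            "cnorm": ParameterQuantiles(0.46, 0.33, 0.58),
        },
        "sa": {
            "r1norm": ParameterQuantiles(0.03, 0.02, 0.04),
            "cnorm": ParameterQuantiles(1.91, 1.63, 2.26),
        },
        "va": {
            "r1norm": ParameterQuantiles(0.18, 0.08, 0.41),
            "cnorm": ParameterQuantiles(0.47, 0.32, 0.85),
        },
    }
    return NormalizedParameterTable(
        entries=entries,
        provenance=(
            "Ten-patient TEVAR cohort medians (IQR). Vertebral entries were "
            "identified against subclavian pressure waveforms; right-side "
            "arteries reused left-side pressure measurements."),
    )


@dataclass(frozen=True)
class FlowDiameterLaw:
    """Empirical power law Q̄ = k * D^b linking mean flow (mL/s) to diameter (mm).

    Exponents fitted for arch branch arteries fall between 1.6 and 2.4; an
    exponent outside that range triggers a warning, not an error, since the
    coefficients are study-specific and must be supplied by the user.
    """

    k: float
    b: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("coefficient k must be positive")
        if not (1.6 <= self.b <= 2.4):
            warnings.warn(
                f"flow-diameter exponent b={self.b} outside the reported "
                "1.6-2.4 range for arch branch arteries", stacklevel=2)


def mean_arterial_pressure(sbp: float, dbp: float) -> float:
    """MAP = (SBP - DBP)/3 + DBP (systole taken as one third of the cycle)."""
    if not sbp > dbp:
        raise ValueError(f"need sbp > dbp, got {sbp} <= {dbp}")
    return (sbp - dbp) / 3.0 + dbp


def total_resistance(mean_pressure: float, mean_flow: float) -> float:
    """Total resistance Rtot = P̄/Q̄ (mmHg·s/mL; P̄ in mmHg, Q̄ in mL/s)."""
    if mean_pressure <= 0 or mean_flow <= 0:
        raise ValueError("mean pressure and mean flow must both be positive")
    return mean_pressure / mean_flow


def normalize_params(params: WK3Params, period: float) -> NormalizedWK3Params:
    """Dimensionless parameters: r1norm = R1/Rtot, cnorm = Rtot*C/T."""
    if period <= 0:
        raise ValueError("period must be positive")
    return NormalizedWK3Params(r1norm=params.r1 / params.rtot,
                               cnorm=params.rtot * params.c / period)


def denormalize_params(nparams: NormalizedWK3Params, rtot: float,
                       period: float) -> WK3Params:
    """Rescale normalized parameters to a patient's Rtot and period."""
    if rtot <= 0 or period <= 0:
        raise ValueError("rtot and period must be positive")
    return WK3Params(r1=nparams.r1norm * rtot,
                     r2=nparams.r2norm * rtot,
                     c=nparams.cnorm * period / rtot)


def mean_flow_from_diameter(diameter: float, law: FlowDiameterLaw) -> float:
    """Mean flow in mL/s from lumen diameter in mm via Q̄ = k * D^b."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return law.k * diameter ** law.b


def estimate_wk3_noninvasive(clinical: ClinicalScalars,
                             table: NormalizedParameterTable | None = None,
                             law: FlowDiameterLaw | None = None) -> WK3Params:
    """Estimate patient-specific WK3 parameters without invasive waveforms.

    Chains MAP from the cuff pressures, Rtot = MAP/Q̄ (Q̄ measured or from
    the flow-diameter law), T = 60/HR, and the artery's cohort-median
    normalized parameters rescaled to (Rtot, T).
    """
    table = table or default_table()
    pbar = mean_arterial_pressure(clinical.sbp, clinical.dbp)
    if clinical.mean_flow is not None:
        qbar = clinical.mean_flow
    elif law is not None:
        qbar = mean_flow_from_diameter(clinical.diameter, law)
    else:
        raise ValueError("mean_flow not given and no flow-diameter law supplied")
    rtot = total_resistance(pbar, qbar)
    nparams = table.median_params(clinical.artery)
    return denormalize_params(nparams, rtot, clinical.period)
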