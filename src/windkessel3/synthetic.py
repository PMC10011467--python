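"""Synthetic patients for exercising the full estimation pipeline.

No raw patient recordings ship with the package, so every pipeline stage is
tested against generated data with known ground truth.  A synthetic patient
is built from

* an artery-specific normalized flow template — a truncated Fourier series
  shaped by a systolic peak ratio, an optional early-diastolic reversal
  depth (subclavian only) and the systolic fraction of the cycle, matching
  the qualitative morphology classes of arch-branch Doppler waveforms
  (mono-phasic carotid/vertebral, sharp-peaked subclavian with reversal);
* clinical scalars drawn from cohort statistics: mean flow (lognormal,
  moment-matched to the reported mean ± SD per artery), mean pressure
  (normal), heart rate (normal);
* normalized WK3 parameters drawn lognormally around the cohort medians
  with spread matched to the reported interquartile ranges.

The pressure waveform is the exact forward simulation of the drawn
parameters applied to the dimensional flow, plus additive Gaussian noise;
cuff-style SBP/DBP are the extrema of the noiseless simulated pressure.
Ground truth is always carried alongside the generated data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .estimation import PatientRecord
from .pipeline import (ClinicalScalars, NormalizedWK3Params, default_table,
                       denormalize_params)
from .waveforms import (GRID, NormalizedWaveform, Waveform, read_waveform,
                        write_waveform)
from .wk3 import SolverSettings, WK3Params, simulate_pressure

__all__ = [
    "FlowTemplateParams",
    "ArteryConfig",
    "CohortConfig",
    "SyntheticPatient",
    "default_cohort_config",
    "make_flow_template",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "read_cohort_manifest",
]

# quartile z-score of the standard normal, used to map an IQR to a lognormal sigma
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class FlowTemplateParams:
    """Shape parameters of an artery-specific normalized flow template.

    peak_ratio : systolic peak over mean (dimensionless, > 1).
    reversal_depth : most negative value over mean (≤ 0; subclavian only,
        0 disables the reversal lobe).
    systolic_fraction : fraction of the period occupied by systole.
    harmonics : Fourier modes retained (controls smoothness/sharpness).
    """

    artery: str
    peak_ratio: float
    reversal_depth: float = 0.0
    systolic_fraction: float = 1.0 / 3.0
    harmonics: int = 12

    def __post_init__(self) -> None:
        if self.peak_ratio <= 1.0:
            raise ValueError("peak_ratio must exceed 1")
        if self.reversal_depth > 0.0:
            raise ValueError("reversal_depth must be ≤ 0 (value/mean of the dip)")
        if self.reversal_depth < 0.0 and self.artery in ("cca", "va"):
            raise ValueError(
                f"flow reversal is a subclavian feature; not allowed for {self.artery!r}")
        if not (0.1 <= self.systolic_fraction <= 0.6):
            raise ValueError("systolic_fraction must lie in [0.1, 0.6]")
        if self.harmonics < 4:
            raise ValueError("need at least 4 harmonics")


#: Default template shapes per artery (peak ratios and the subclavian
#: reversal chosen to mimic published arch-branch Doppler morphologies).
DEFAULT_TEMPLATES: Mapping[str, FlowTemplateParams] = {
    "cca": FlowTemplateParams(artery="cca", peak_ratio=2.0),
    "sa": FlowTemplateParams(artery="sa", peak_ratio=4.0, reversal_depth=-0.5),
    "va": FlowTemplateParams(artery="va", peak_ratio=1.7),
}


def _wrapped_gaussian(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    d = tau - center
    d -= np.round(d)
    return np.exp(-0.5 * (d / width) ** 2)


def _truncate(values: np.ndarray, harmonics: int, n_out: int | None = None) -> np.ndarray:
    """Keep Fourier modes 0..harmonics; optionally resample to n_out points."""
    n_in = values.size
    spec = np.fft.rfft(values) / n_in
    n_out = n_out or n_in
    out = np.zeros(n_out // 2 + 1, dtype=complex)
    keep = min(harmonics + 1, out.size, spec.size)
    out[:keep] = spec[:keep]
    return np.fft.irfft(out * n_out, n=n_out)


def make_flow_template(params: FlowTemplateParams) -> NormalizedWaveform:
    """Build a smooth unit-mean flow template with the requested morphology.

    A wrapped Gaussian systolic lobe (plus, for the subclavian, a negative
    early-diastolic lobe) is Fourier-truncated and its amplitudes iterated
    so the final peak and dip hit ``peak_ratio`` and ``reversal_depth``.
    """
    nfine = 1024
    tau = np.arange(nfine) / nfine
    sf = params.systolic_fraction
    g1 = _wrapped_gaussian(tau, 0.45 * sf, 0.16 * sf)
    reversal = params.reversal_depth < 0.0
    g2 = _wrapped_gaussian(tau, 1.30 * sf, 0.13 * sf) if reversal else None

    a = params.peak_ratio - 1.0
    b = 1.0 - params.reversal_depth if reversal else 0.0
    q = np.ones(nfine)
    for _ in range(60):
        base = a * g1 - (b * g2 if reversal else 0.0)
        base = base - base.mean()
        q = _truncate(1.0 + base, params.harmonics)
        q = q / q.mean()
        peak_err = (params.peak_ratio - 1.0) / max(q.max() - 1.0, 1e-9)
        a *= np.clip(peak_err, 0.5, 2.0)
        if reversal:
            dip_err = (1.0 - params.reversal_depth) / max(1.0 - q.min(), 1e-9)
            b *= np.clip(dip_err, 0.5, 2.0)
    base = a * g1 - (b * g2 if reversal else 0.0)
    base = base - base.mean()
    vals = _truncate(1.0 + base, params.harmonics, n_out=GRID.size)
    vals = vals / vals.mean()
    return NormalizedWaveform(value=vals, quantity="flow")


@dataclass(frozen=True)
class ArteryConfig:
    """Cohort distributions for one artery (mean ± SD parameterisations)."""

    mean_flow_ml_min: tuple[float, float]
    mean_pressure_mmhg: tuple[float, float]
    template: FlowTemplateParams


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for synthetic cohort generation.

    Defaults reproduce the source cohort: mean flows 458 ± 139 (CCA),
    185 ± 116 (SA), 90 ± 59 (VA) mL/min; mean pressures 83 ± 11 (CCA) and
    85 ± 12 (SA, reused for VA) mmHg; heart rate 63 ± 10 bpm.  Normalized
    parameters are drawn lognormally around the cohort medians with sigma
    matched to the published IQRs (scaled by ``param_sigma_scale``).
    Template shapes receive a mild lognormal jitter so patients differ in
    waveform morphology, not just scale.
    """

    arteries: Mapping[str, ArteryConfig]
    heart_rate_bpm: tuple[float, float] = (63.0, 10.0)
    pressure_noise_sd: float = 1.0
    n_patients: int = 10
    seed: int = 0
    param_sigma_scale: float = 1.0
    template_jitter: float = 0.08
    max_redraws: int = 100

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be at least 1")
        if self.pressure_noise_sd < 0:
            raise ValueError("pressure noise sd cannot be negative")


def default_cohort_config(n_patients: int = 10, seed: int = 0,
                          pressure_noise_sd: float = 1.0,
                          param_sigma_scale: float = 1.0) -> CohortConfig:
    """Cohort configuration with the shipped per-artery statistics."""
    arteries = {
        "cca": ArteryConfig((458.0, 139.0), (83.0, 11.0), DEFAULT_TEMPLATES["cca"]),
        "sa": ArteryConfig((185.0, 116.0), (85.0, 12.0), DEFAULT_TEMPLATES["sa"]),
        # no vertebral pressure statistics exist (subclavian pressure was
        # used for vertebral fits); the SA distribution is reused here
        "va": ArteryConfig((90.0, 59.0), (85.0, 12.0), DEFAULT_TEMPLATES["va"]),
    }
    return CohortConfig(arteries=arteries, n_patients=n_patients, seed=seed,
                        pressure_noise_sd=pressure_noise_sd,
                        param_sigma_scale=param_sigma_scale)


@dataclass(frozen=True)
class SyntheticPatient:
    """Generated patient: ground truth, waveforms and derived clinical scalars."""

    patient_id: str
    artery: str
    true_params: WK3Params
    true_normalized: NormalizedWK3Params
    flow: Waveform
    pressure: Waveform
    clinical: ClinicalScalars

    def record(self) -> PatientRecord:
        return PatientRecord(patient_id=self.patient_id, artery=self.artery,
                             flow=self.flow, pressure=self.pressure)


def _lognormal_from_mean_sd(rng, mean: float, sd: float) -> float:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _draw_positive_normal(rng, mean: float, sd: float, lo: float, hi: float,
                          max_redraws: int, what: str) -> float:
    for _ in range(max_redraws):
        x = float(rng.normal(mean, sd))
        if lo < x < hi:
            return x
    raise RuntimeError(f"could not draw a valid {what} within {max_redraws} tries")


def _draw_lognormal_median(rng, median: float, sigma: float, hi: float,
                           max_redraws: int, what: str) -> float:
    for _ in range(max_redraws):
        x = float(rng.lognormal(np.log(median), sigma))
        if 0.0 < x < hi:
            return x
    raise RuntimeError(f"could not draw a valid {what} within {max_redraws} tries")


def generate_patient(artery: str, config: CohortConfig, rng,
                     patient_id: str = "p0",
                     solver: SolverSettings | None = None) -> SyntheticPatient:
    """Draw one synthetic patient for the given artery.

    Draw order (fixed, for reproducibility): mean flow, mean pressure, heart
    rate, r1norm, cnorm, template jitters, pressure noise.
    """
    if artery not in config.arteries:
        raise KeyError(f"artery {artery!r} not configured")
    acfg = config.arteries[artery]
    table = default_table()
    q_r1 = table.entries[artery]["r1norm"]
    q_cn = table.entries[artery]["cnorm"]
    s = config.param_sigma_scale
    sigma_r1 = s * np.log(q_r1.q75 / q_r1.q25) / (2.0 * _Z75)
    sigma_cn = s * np.log(q_cn.q75 / q_cn.q25) / (2.0 * _Z75)

    qbar = _lognormal_from_mean_sd(rng, *acfg.mean_flow_ml_min) / 60.0  # mL/s
    pbar = _draw_positive_normal(rng, *acfg.mean_pressure_mmhg, lo=30.0, hi=200.0,
                                 max_redraws=config.max_redraws, what="mean pressure")
    hr = _draw_positive_normal(rng, *config.heart_rate_bpm, lo=30.0, hi=150.0,
                               max_redraws=config.max_redraws, what="heart rate")
    r1norm = _draw_lognormal_median(rng, q_r1.median, sigma_r1, hi=0.8,
                                    max_redraws=config.max_redraws, what="r1norm")
    cnorm = _draw_lognormal_median(rng, q_cn.median, sigma_cn, hi=8.0,
                                   max_redraws=config.max_redraws, what="cnorm")

    tmpl = acfg.template
    if config.template_jitter > 0:
        jitter = lambda: float(np.exp(rng.normal(0.0, config.template_jitter)))
        tmpl = replace(tmpl,
                       peak_ratio=1.0 + (tmpl.peak_ratio - 1.0) * jitter(),
                       reversal_depth=tmpl.reversal_depth * jitter())
    template = make_flow_template(tmpl)

    T = 60.0 / hr
    rtot = pbar / qbar
    nparams = NormalizedWK3Params(r1norm=r1norm, cnorm=cnorm)
    params = denormalize_params(nparams, rtot, T)
    flow = template.to_waveform(mean=qbar, period=T)
    pressure_clean = simulate_pressure(flow, params, solver)
    sbp = float(np.max(pressure_clean.value))
    dbp = float(np.min(pressure_clean.value))
    noise = rng.normal(0.0, config.pressure_noise_sd, pressure_clean.value.size) \
        if config.pressure_noise_sd > 0 else 0.0
    pressure = Waveform(time=pressure_clean.time,
                        value=pressure_clean.value + noise,
                        period=T, quantity="pressure")
    clinical = ClinicalScalars(sbp=sbp, dbp=dbp, heart_rate=hr, artery=artery,
                               mean_flow=qbar)
    return SyntheticPatient(patient_id=patient_id, artery=artery,
                            true_params=params, true_normalized=nparams,
                            flow=flow, pressure=pressure, clinical=clinical)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated patients plus a tabular manifest."""

    patients: tuple
    manifest: pd.DataFrame
    config: CohortConfig

    def records(self) -> list[PatientRecord]:
        return [p.record() for p in self.patients]


def generate_cohort(config: CohortConfig,
                    solver: SolverSettings | None = None) -> SyntheticCohort:
    """Generate ``n_patients`` per configured artery with one seeded RNG."""
    rng = np.random.default_rng(config.seed)
    patients = []
    rows = []
    for artery in config.arteries:
        for i in range(config.n_patients):
            pid = f"{artery}{i:03d}"
            pat = generate_patient(artery, config, rng, patient_id=pid,
                                   solver=solver)
            patients.append(pat)
            rows.append({
                "patient_id": pid, "artery": artery,
                "heart_rate_bpm": pat.clinical.heart_rate,
                "mean_flow_ml_s": pat.clinical.mean_flow,
                "sbp_mmhg": pat.clinical.sbp, "dbp_mmhg": pat.clinical.dbp,
                "true_r1": pat.true_params.r1, "true_r2": pat.true_params.r2,
                "true_c": pat.true_params.c,
                "true_r1norm": pat.true_normalized.r1norm,
                "true_cnorm": pat.true_normalized.cnorm,
            })
    return SyntheticCohort(patients=tuple(patients),
                           manifest=pd.DataFrame(rows), config=config)


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write waveform CSVs, manifest.csv and truth.json to a directory.

    Ground truth is always serialized alongside the generated data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth = {"seed": cohort.config.seed,
             "pressure_noise_sd": cohort.config.pressure_noise_sd,
             "patients": {}}
    for pat in cohort.patients:
        flow_file = f"{pat.patient_id}_flow.csv"
        pressure_file = f"{pat.patient_id}_pressure.csv"
        write_waveform(pat.flow, outdir / flow_file)
        write_waveform(pat.pressure, outdir / pressure_file)
        rows.append({"patient_id": pat.patient_id, "artery": pat.artery,
                     "flow_csv": flow_file, "pressure_csv": pressure_file})
        truth["patients"][pat.patient_id] = {
            "artery": pat.artery,
            "r1": pat.true_params.r1, "r2": pat.true_params.r2,
            "c": pat.true_params.c,
            "r1norm": pat.true_normalized.r1norm,
            "cnorm": pat.true_normalized.cnorm,
            "heart_rate_bpm": pat.clinical.heart_rate,
            "sbp_mmhg": pat.clinical.sbp, "dbp_mmhg": pat.clinical.dbp,
        }
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_cohort_manifest(path) -> list[PatientRecord]:
    """Load patient records listed in a manifest CSV (paths relative to it)."""
    path = Path(path)
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        flow = read_waveform(path.parent / row["flow_csv"])
        pressure = read_waveform(path.parent / row["pressure_csv"])
        records.append(PatientRecord(patient_id=str(row["patient_id"]),
                                     artery=str(row["artery"]),
                                     flow=flow, pressure=pressure))
    return records
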