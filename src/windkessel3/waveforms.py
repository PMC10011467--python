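"""Single-period arterial flow and pressure waveforms.

A :class:`Waveform` holds one cardiac period of a sampled quantity — flow in
mL/s or pressure in mmHg — together with the cardiac period ``T``.  Waveforms
are treated as periodic: the value at ``t = t0 + T`` equals the value at
``t0`` by construction, and interpolation between samples uses a periodic
cubic spline so that the time derivative needed by the Windkessel ODE is
smooth.

A :class:`NormalizedWaveform` is the dimensionless form used throughout the
normalization pipeline: time divided by the period, values divided by the
period mean, resampled onto the uniform 100-point grid ``{0, 0.01, …, 0.99}``
(the period endpoint is excluded so it is not double counted).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "GRID",
    "Waveform",
    "NormalizedWaveform",
    "WaveformEnsemble",
    "PeriodicInterpolant",
    "read_waveform",
    "write_waveform",
    "write_ensemble",
    "waveform_mean",
    "normalize_waveform",
    "average_waveforms",
    "smooth_pressure_trace",
]

#: Dimensionless time grid on [0, 1): 100 uniform points, step 0.01.
GRID: np.ndarray = np.arange(100) / 100.0

Quantity = Literal["flow", "pressure"]

_VALID_QUANTITIES = ("flow", "pressure")


class WaveformError(ValueError):
    """Raised for invalid waveform data or malformed waveform files."""


class PeriodicInterpolant:
    """Periodic interpolant of one-period samples.

    Parameters
    ----------
    time, value : arrays of the samples (time strictly increasing, spanning
        less than one period).
    period : the cardiac period; the sample at ``time[0] + period`` is taken
        equal to the first sample.
    kind : ``"cubic"`` (periodic cubic spline, default) or ``"linear"``.
    """

    def __init__(self, time: np.ndarray, value: np.ndarray, period: float,
                 kind: str = "cubic") -> None:
        self.t0 = float(time[0])
        self.period = float(period)
        self.kind = kind
        te = np.append(time, time[0] + period)
        ve = np.append(value, value[0])
        if kind == "cubic":
            self._cs = CubicSpline(te, ve, bc_type="periodic")
        elif kind == "linear":
            self._te, self._ve = te, ve
            self._cs = None
        else:
            raise ValueError(f"unknown interpolation kind {kind!r}")

    def _wrap(self, t):
        return self.t0 + np.mod(np.asarray(t, dtype=float) - self.t0, self.period)

    def __call__(self, t):
        tw = self._wrap(t)
        if self._cs is not None:
            return self._cs(tw)
        return np.interp(tw, self._te, self._ve)

    def derivative(self, t):
        """First time derivative (analytic for the cubic spline)."""
        tw = self._wrap(t)
        if self._cs is not None:
            return self._cs(tw, 1)
        # one-sided finite difference of the linear interpolant
        h = self.period * 1e-6
        return (self(tw + h) - self(tw - h)) / (2 * h)


@dataclass(frozen=True)
class Waveform:
    """One cardiac period of a sampled flow (mL/s) or pressure (mmHg) trace.

    Attributes
    ----------
    time : sample times in seconds, strictly increasing, ``time[0] >= 0``,
        spanning less than one period.
    value : sampled values; pressure must be positive, flow may reverse sign.
    period : cardiac period T in seconds.
    quantity : ``"flow"`` or ``"pressure"``.
    """

    time: np.ndarray
    value: np.ndarray
    period: float
    quantity: str

    def __post_init__(self) -> None:
        t = np.atleast_1d(np.asarray(self.time, dtype=float))
        v = np.atleast_1d(np.asarray(self.value, dtype=float))
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)
        object.__setattr__(self, "period", float(self.period))
        if self.quantity not in _VALID_QUANTITIES:
            raise WaveformError(f"quantity must be one of {_VALID_QUANTITIES}, got {self.quantity!r}")
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise WaveformError("time and value must be 1-D arrays of equal length")
        if t.size < 2:
            raise WaveformError("waveform needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise WaveformError("waveform contains non-finite samples")
        if np.any(np.diff(t) <= 0):
            raise WaveformError("non-monotone time samples")
        if self.period <= 0:
            raise WaveformError("period must be positive")
        if t[0] < 0:
            raise WaveformError("time must start at or after 0")
        if t[-1] > self.period * (1 + 1e-12):
            raise WaveformError("time samples exceed the declared period")
        if t[-1] - t[0] >= self.period:
            raise WaveformError("samples span a full period or more; drop the wrapped endpoint")
        if self.quantity == "pressure" and np.any(v <= 0):
            raise WaveformError("pressure values must be positive")

    @cached_property
    def _spline(self) -> PeriodicInterpolant:
        return PeriodicInterpolant(self.time, self.value, self.period)

    def interpolant(self, kind: str = "cubic") -> PeriodicInterpolant:
        """Periodic interpolant of the samples (cached for the cubic kind)."""
        if kind == "cubic":
            return self._spline
        return PeriodicInterpolant(self.time, self.value, self.period, kind=kind)

    def mean(self) -> float:
        """Period mean (periodic trapezoidal rule), same units as ``value``."""
        return waveform_mean(self)


@dataclass(frozen=True)
class NormalizedWaveform:
    """Dimensionless waveform on the uniform 100-point grid [0, 1).

    Values have unit mean over the period (the grid mean equals 1 to within
    1e-9 by construction); flow may dip negative during diastolic reversal.
    """

    value: np.ndarray
    quantity: str

    def __post_init__(self) -> None:
        v = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "value", v)
        if self.quantity not in _VALID_QUANTITIES:
            raise WaveformError(f"quantity must be one of {_VALID_QUANTITIES}, got {self.quantity!r}")
        if v.shape != (GRID.size,):
            raise WaveformError(f"normalized waveform must have {GRID.size} samples on the 0.01 grid")
        if not np.all(np.isfinite(v)):
            raise WaveformError("normalized waveform contains non-finite samples")
        if abs(v.mean() - 1.0) > 1e-9:
            raise WaveformError("normalized waveform mean must equal 1 within 1e-9")

    @property
    def grid(self) -> np.ndarray:
        return GRID

    def interpolant(self, kind: str = "cubic") -> PeriodicInterpolant:
        return PeriodicInterpolant(GRID, self.value, 1.0, kind=kind)

    def to_waveform(self, mean: float, period: float) -> Waveform:
        """Rescale to a dimensional waveform with the given mean and period."""
        return Waveform(time=GRID * period, value=self.value * mean,
                        period=period, quantity=self.quantity)


@dataclass(frozen=True)
class WaveformEnsemble:
    """A set of normalized waveforms with their pointwise mean and spread."""

    members: tuple
    pointwise_mean: NormalizedWaveform
    pointwise_sd: np.ndarray


def waveform_mean(w: Waveform) -> float:
    """Period average of a waveform by the periodic trapezoidal rule.

    The wrap-around segment from the last sample back to the first (one
    period later) is included, so the result is the true mean of the
    periodic extension.
    """
    t = np.append(w.time, w.time[0] + w.period)
    v = np.append(w.value, w.value[0])
    return float(np.trapezoid(v, t) / w.period)


def normalize_waveform(w: Waveform) -> NormalizedWaveform:
    """Normalize a waveform by its period mean and resample onto [0, 1).

    Time is divided by the period and values by the period mean, then the
    result is resampled by periodic cubic interpolation onto the uniform
    0.01 grid.  The output grid mean is renormalized to exactly 1 so that
    normalization is idempotent and the unit-mean invariant is exact.
    """
    m = waveform_mean(w)
    scale = float(np.max(np.abs(w.value))) or 1.0
    if abs(m) < 1e-12 * scale:
        raise WaveformError("waveform mean is (numerically) zero; normalization undefined")
    vals = np.asarray(w.interpolant()(GRID * w.period), dtype=float) / m
    vals = vals / vals.mean()
    return NormalizedWaveform(value=vals, quantity=w.quantity)


def average_waveforms(members: Sequence[NormalizedWaveform]) -> WaveformEnsemble:
    """Pointwise mean and standard deviation of normalized waveforms.

    All members must share the same quantity.  The pointwise mean of
    unit-mean members has unit mean itself, so it is returned as a
    :class:`NormalizedWaveform` without rescaling.
    """
    members = tuple(members)
    if not members:
        raise WaveformError("cannot average an empty ensemble")
    quantities = {m.quantity for m in members}
    if len(quantities) > 1:
        raise WaveformError(f"mixed quantities in ensemble: {sorted(quantities)}")
    stack = np.stack([m.value for m in members])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0)
    return WaveformEnsemble(
        members=members,
        pointwise_mean=NormalizedWaveform(value=mean / mean.mean(), quantity=members[0].quantity),
        pointwise_sd=sd,
    )


def smooth_pressure_trace(raw: Waveform, heart_rate: float, n_harmonics: int = 10,
                          n_out: int = 200) -> Waveform:
    """Extract and smooth one representative period from a pressure recording.

    The recording (a :class:`Waveform` whose ``period`` field is the full
    recording length) must cover at least one cardiac period at the given
    heart rate.  Whole cycles are phase-averaged, then low-pass filtered by
    keeping the first ``n_harmonics`` harmonics of the cardiac frequency
    (zero-phase, by Fourier truncation).  The DC component is untouched, so
    the cycle-average mean is preserved exactly by the filter.

    Parameters
    ----------
    raw : recording; ``raw.period`` is interpreted as the recording length.
    heart_rate : beats per minute; the extracted period is ``60 / heart_rate``.
    n_harmonics : harmonics of the cardiac frequency retained (default 10).
    n_out : samples in the returned single-period waveform.
    """
    if heart_rate <= 0:
        raise WaveformError("heart rate must be positive")
    T = 60.0 / heart_rate
    duration = float(raw.time[-1] - raw.time[0])
    n_cycles = int(np.floor(duration / T * (1 + 1e-9)))
    if n_cycles < 1:
        raise WaveformError(
            f"recording spans {duration:.3f} s, shorter than one cardiac period ({T:.3f} s)")
    k = 1024
    tf = raw.time[0] + np.arange(n_cycles * k) * (T / k)
    vf = np.interp(tf, raw.time, raw.value)
    beat = vf.reshape(n_cycles, k).mean(axis=0)
    spec = np.fft.rfft(beat) / k
    spec[n_harmonics + 1:] = 0.0
    out_spec = np.zeros(n_out // 2 + 1, dtype=complex)
    nkeep = min(n_harmonics + 1, out_spec.size)
    out_spec[:nkeep] = spec[:nkeep]
    vals = np.fft.irfft(out_spec * n_out, n=n_out)
    return Waveform(time=np.arange(n_out) * (T / n_out), value=vals,
                    period=T, quantity=raw.quantity)


# ---------------------------------------------------------------------------
# CSV I/O
#
# Format: one metadata comment line, then a column-header row and data rows:
#   # quantity=flow units=mL/s period_s=0.952
#   time_s,value
#   0,5.2
#   ...

def _parse_header(line: str) -> dict:
    meta = {}
    for token in line.lstrip("#").split():
        if "=" in token:
            key, _, val = token.partition("=")
            meta[key.strip()] = val.strip()
    return meta


def read_waveform(path, quantity: str | None = None,
                  flow_units: str | None = None) -> Waveform:
    """Read a waveform CSV.

    The metadata line must declare the quantity, units and period.  Flow in
    mL/min is converted to mL/s on read, so the returned waveform always has
    units mL/s (flow) or mmHg (pressure).  Explicit ``quantity`` /
    ``flow_units`` arguments override absent header fields and must agree
    with present ones.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if not lines or not lines[0].lstrip().startswith("#"):
        raise WaveformError(f"{path}: missing '# quantity=... units=... period_s=...' header line")
    meta = _parse_header(lines[0])
    if "period_s" not in meta:
        raise WaveformError(f"{path}: missing period (period_s=...) in header")
    period = float(meta["period_s"])
    q = meta.get("quantity", quantity)
    if q is None:
        raise WaveformError(f"{path}: quantity not declared in header or arguments")
    if quantity is not None and q != quantity:
        raise WaveformError(f"{path}: header quantity {q!r} != requested {quantity!r}")
    units = meta.get("units", flow_units if q == "flow" else "mmHg")
    if flow_units is not None and q == "flow" and units != flow_units:
        raise WaveformError(f"{path}: header units {units!r} != requested {flow_units!r}")

    body = "\n".join(lines[1:])
    df = pd.read_csv(io.StringIO(body))
    if df.shape[1] < 2:
        raise WaveformError(f"{path}: expected two columns (time_s,value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(v)):
        raise WaveformError(f"{path}: NaN or infinite samples")
    if np.any(np.diff(t) <= 0):
        raise WaveformError(f"{path}: non-monotone time")
    # drop a wrapped endpoint (t[-1] == t[0] + period) — the period closure is implicit
    if t.size >= 2 and t[-1] - t[0] >= period * (1 - 1e-9):
        t, v = t[:-1], v[:-1]
    if q == "flow":
        if units not in ("mL/s", "mL/min"):
            raise WaveformError(f"{path}: flow units must be mL/s or mL/min, got {units!r}")
        if units == "mL/min":
            v = v / 60.0
    elif units not in ("mmHg",):
        raise WaveformError(f"{path}: pressure units must be mmHg, got {units!r}")
    return Waveform(time=t, value=v, period=period, quantity=q)


def write_waveform(w: Waveform, path) -> None:
    """Write a waveform CSV (internal units: mL/s or mmHg; 6 significant digits)."""
    units = "mL/s" if w.quantity == "flow" else "mmHg"
    with open(path, "w") as fh:
        fh.write(f"# quantity={w.quantity} units={units} period_s={w.period:.9g}\n")
        fh.write("time_s,value\n")
        for t, v in zip(w.time, w.value):
            fh.write(f"{t:.6g},{v:.6g}\n")


def write_ensemble(ens: WaveformEnsemble, path) -> None:
    """Write an ensemble's grid, pointwise mean and sd as CSV."""
    pd.DataFrame({
        "grid": GRID,
        "mean": ens.pointwise_mean.value,
        "sd": ens.pointwise_sd,
    }).to_csv(path, index=False)
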