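"""Monte Carlo sensitivity of the predicted pressure to (r1norm, cnorm).

Given reference normalized flow and pressure waveforms (typically ensemble
means over an artery class), ``n`` parameter pairs are drawn uniformly over
configurable ranges; for each draw the normalized forward model is run and
the cost — the sum of squared differences to the reference pressure over
the 100-point grid — is recorded.  The resulting scatter can be gridded
into a contour surface whose low-cost basin shows which parameter
combinations the pressure waveform can and cannot distinguish.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import griddata

from .waveforms import NormalizedWaveform
from .wk3 import NormalizedPressureSimulator, SolverSettings

__all__ = [
    "DEFAULT_RANGES",
    "SensitivityMap",
    "ContourSurface",
    "monte_carlo_sensitivity",
    "grid_contour",
]

#: Default sampling ranges: (r1norm_lo, r1norm_hi, cnorm_lo, cnorm_hi).
DEFAULT_RANGES: tuple[float, float, float, float] = (0.001, 0.6, 0.01, 3.0)


@dataclass(frozen=True)
class SensitivityMap:
    """Monte Carlo samples of the pressure-match cost in normalized space.

    ``samples`` has columns r1norm, cnorm, cost; the seed and ranges are
    recorded so any map is reproducible bit-for-bit.
    """

    samples: pd.DataFrame
    ranges: tuple[float, float, float, float]
    n: int
    seed: int
    reference_flow: NormalizedWaveform
    reference_pressure: NormalizedWaveform
    solver: SolverSettings

    def argmin(self) -> pd.Series:
        return self.samples.loc[self.samples["cost"].idxmin()]


@dataclass(frozen=True)
class ContourSurface:
    """Gridded cost surface for contour plotting or CSV export."""

    r1norm_axis: np.ndarray
    cnorm_axis: np.ndarray
    cost: np.ndarray  # shape (len(cnorm_axis), len(r1norm_axis))
    argmin: pd.Series
    reference_point: tuple[float, float] | None = None
    reference_cost: float | None = None


def _cost(sim: NormalizedPressureSimulator, p_ref: np.ndarray,
          r1norm: float, cnorm: float) -> float:
    p = sim.run(r1norm, cnorm)
    return float(np.sum((p - p_ref) ** 2))


def monte_carlo_sensitivity(flow_norm: NormalizedWaveform,
                            pressure_norm: NormalizedWaveform,
                            n: int = 1500,
                            ranges: tuple[float, float, float, float] = DEFAULT_RANGES,
                            seed: int = 0,
                            solver: SolverSettings | None = None,
                            include_points: Sequence[tuple[float, float]] = ()) -> SensitivityMap:
    """Uniform Monte Carlo map of the pressure-match cost over (r1norm, cnorm).

    All ``n`` draws are evaluated exhaustively and the full sample list is
    returned (the minimum is a query on the result, not an early stop).
    ``include_points`` appends deterministic parameter pairs (e.g. known
    generating values or cohort medians) after the random draws; they count
    towards the recorded sample size.
    """
    r1lo, r1hi, clo, chi = ranges
    if not (0 < r1lo < r1hi < 1 and 0 < clo < chi):
        raise ValueError(f"empty or invalid sampling ranges {ranges}")
    if n < 1:
        raise ValueError("n must be at least 1")
    solver = solver or SolverSettings()
    rng = np.random.default_rng(seed)
    r1 = rng.uniform(r1lo, r1hi, n)
    cn = rng.uniform(clo, chi, n)
    if include_points:
        extra = np.asarray(include_points, dtype=float)
        r1 = np.concatenate([r1, extra[:, 0]])
        cn = np.concatenate([cn, extra[:, 1]])
    sim = NormalizedPressureSimulator(flow_norm, solver)
    p_ref = pressure_norm.value
    cost = np.array([_cost(sim, p_ref, a, b) for a, b in zip(r1, cn)])
    samples = pd.DataFrame({"r1norm": r1, "cnorm": cn, "cost": cost})
    return SensitivityMap(samples=samples, ranges=ranges, n=len(samples),
                          seed=seed, reference_flow=flow_norm,
                          reference_pressure=pressure_norm, solver=solver)


def grid_contour(map_: SensitivityMap, grid_resolution: int = 50,
                 reference_point: tuple[float, float] | None = None) -> ContourSurface:
    """Grid the scattered costs onto a regular (r1norm, cnorm) surface.

    Nearest-sample interpolation (axes rescaled by their ranges first so the
    metric is isotropic); the grid cell nearest the best sample is set to
    that sample's exact cost, so the surface minimum always equals the
    sample minimum.  When ``reference_point`` is given its cost is computed
    by a fresh simulation against the stored reference waveforms.
    """
    if grid_resolution < 2:
        raise ValueError("grid_resolution must be at least 2")
    if map_.samples.empty:
        raise ValueError("empty sensitivity map")
    r1lo, r1hi, clo, chi = map_.ranges
    xs = np.linspace(r1lo, r1hi, grid_resolution)
    ys = np.linspace(clo, chi, grid_resolution)
    pts = map_.samples[["r1norm", "cnorm"]].to_numpy()
    scale = np.array([r1hi - r1lo, chi - clo])
    gx, gy = np.meshgrid(xs, ys)
    grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
    cost = griddata(pts / scale, map_.samples["cost"].to_numpy(),
                    grid_pts / scale, method="nearest").reshape(gy.shape)
    best = map_.argmin()
    ix = int(np.argmin(np.abs(xs - best["r1norm"])))
    iy = int(np.argmin(np.abs(ys - best["cnorm"])))
    cost[iy, ix] = best["cost"]

    ref_cost = None
    if reference_point is not None:
        sim = NormalizedPressureSimulator(map_.reference_flow, map_.solver)
        ref_cost = _cost(sim, map_.reference_pressure.value, *reference_point)
    return ContourSurface(r1norm_axis=xs, cnorm_axis=ys, cost=cost,
                          argmin=best, reference_point=reference_point,
                          reference_cost=ref_cost)
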