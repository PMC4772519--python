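"""Synthetic inputs: mouse-like sparse measurements, robust smoothing,
interpolated 30-minute replicate datasets, and noisy model samples.

The measurement emulation mirrors the structure of the implant experiment:
residual histamine measured at 0, 2, 4, 8, 12, 16 h and PMN / MPhi at
0, 4, 8, 12, 16 h, four animals per time point.  Values are produced by the
model at the packaged reference parameters with multiplicative lognormal
replicate scatter, which reproduces the qualitative shape of the real
measurements (early histamine decay, recovery with damped oscillation,
monotone phagocyte accumulation) but none of their absolute scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .fitting import SPECIES_TO_STATE, TimeSeriesDataset
from .model import PerturbationSchedule
from .parameters import ModelParameters, reference_parameters
from .simulate import default_initial_state, simulate

__all__ = [
    "MEASUREMENT_TIMES",
    "NoiseSpec",
    "mouse_fixture",
    "iwm_smooth",
    "generate_synthetic_datasets",
    "simulate_noisy",
]

#: Measurement schedule of the emulated experiment (hours).
MEASUREMENT_TIMES: dict[str, tuple[float, ...]] = {
    "residual_histamine": (0.0, 2.0, 4.0, 8.0, 12.0, 16.0),
    "pmn": (0.0, 4.0, 8.0, 12.0, 16.0),
    "mphi": (0.0, 4.0, 8.0, 12.0, 16.0),
}

#: Multiplicative replicate scatter (lognormal sigma) of the emulated mice.
REPLICATE_SIGMA = 0.12

N_REPLICATES = 4


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white-noise specification for simulated observations."""

    sigma: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def mouse_fixture(
    seed: int | None = None,
    params: ModelParameters | None = None,
    n_replicates: int = N_REPLICATES,
    scatter: float = REPLICATE_SIGMA,
) -> TimeSeriesDataset:
    """Emulated sparse replicated measurements (4 replicates per time point).

    Simulates the model at the reference parameters (residual histamine
    starting at 1, everything else at 0), samples each species at its
    measurement times, and draws ``n_replicates`` lognormal multiplicative
    replicates per point.  Deterministic given ``seed``.
    """
    p = params or reference_parameters()
    rng = np.random.default_rng(seed)
    grid = np.unique(np.concatenate([np.asarray(v) for v in MEASUREMENT_TIMES.values()]))
    traj = simulate(p, PerturbationSchedule(), grid, default_initial_state())
    records: list[tuple[float, str, int, float]] = []
    for species, times in MEASUREMENT_TIMES.items():
        curve = traj.state(SPECIES_TO_STATE[species])
        for t in times:
            clean = float(curve[np.searchsorted(grid, t)])
            reps = clean * rng.lognormal(0.0, scatter, size=n_replicates)
            for k, v in enumerate(reps):
                records.append((t, species, k, float(v)))
    return TimeSeriesDataset.from_records(records)


def iwm_smooth(
    tbl: TimeSeriesDataset,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Outlier-robust per-time-point mean by iterative reweighting.

    For each (species, time) the estimate starts at the arithmetic mean and
    is refined by weights ``w_k = 1 / (eps + |y_k - m|)`` with
    ``eps = 1e-6 * scale`` until the estimate moves less than ``tol`` (or
    ``max_iter`` sweeps).  ``tol = inf`` returns the plain mean (zero
    iterations).  This is a surrogate for the original iterative weighted
    mean used with the mouse data, built to the same purpose: down-weighting
    outlying replicates.

    Returns ``{species: (times, smoothed values)}`` with times sorted.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for species in tbl.species_present():
        sub = tbl.frame[tbl.frame["species"] == species]
        times = np.unique(sub["time_h"].to_numpy(float))
        smoothed = np.empty_like(times)
        for i, t in enumerate(times):
            y = sub.loc[sub["time_h"] == t, "value"].to_numpy(float)
            if len(y) < 2:
                smoothed[i] = y[0] if len(y) else np.nan
                continue
            m = float(y.mean())
            eps = 1e-6 * max(float(np.abs(y).max()), 1.0)
            for _ in range(max_iter):
                if not math.isfinite(tol):
                    break
                w = 1.0 / (eps + np.abs(y - m))
                m_new = float((w * y).sum() / w.sum())
                if abs(m_new - m) < tol:
                    m = m_new
                    break
                m = m_new
            smoothed[i] = m
        out[species] = (times, smoothed)
    return out


def _replicate_rel_deviations(
    tbl: TimeSeriesDataset, smooth: Mapping[str, tuple[np.ndarray, np.ndarray]]
) -> dict[str, np.ndarray]:
    """Pools of relative replicate deviations (y - s)/s per species, taken at
    time points where the smoothed level is meaningfully positive."""
    pools: dict[str, np.ndarray] = {}
    for species, (times, values) in smooth.items():
        sub = tbl.frame[tbl.frame["species"] == species]
        devs: list[np.ndarray] = []
        scale = float(np.max(values)) if len(values) else 0.0
        for t, s in zip(times, values):
            if s <= 1e-9 * max(scale, 1.0):
                continue  # relative scatter undefined at (near-)zero level
            y = sub.loc[sub["time_h"] == t, "value"].to_numpy(float)
            devs.append((y - s) / s)
        pools[species] = np.concatenate(devs) if devs else np.zeros(1)
    return pools


def generate_synthetic_datasets(
    tbl: TimeSeriesDataset,
    n: int = 100,
    dt: float = 0.5,
    seed: int | None = None,
    horizon: float = 16.0,
) -> list[TimeSeriesDataset]:
    """Replicate datasets on a dense grid from sparse measurements.

    Pipeline: robust-smooth the replicates (:func:`iwm_smooth`), interpolate
    each species to ``0:dt:horizon`` with a shape-preserving monotone cubic
    (PCHIP, no overshoot below zero between non-negative knots), then draw
    ``n`` datasets by applying replicate relative deviations resampled with
    replacement at every grid point.  With zero observed scatter the single
    dataset equals the interpolated curve exactly.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    if dt <= 0:
        raise ValueError("need dt > 0")
    rng = np.random.default_rng(seed)
    smooth = iwm_smooth(tbl)
    pools = _replicate_rel_deviations(tbl, smooth)
    grid = np.round(np.arange(0.0, horizon + dt / 2, dt), 10)
    curves = {
        species: np.clip(PchipInterpolator(times, values)(grid), 0.0, None)
        for species, (times, values) in smooth.items()
    }
    datasets: list[TimeSeriesDataset] = []
    for run in range(n):
        frames = []
        for species, curve in curves.items():
            devs = rng.choice(pools[species], size=len(grid), replace=True)
            values = np.clip(curve * (1.0 + devs), 0.0, None)
            frames.append(pd.DataFrame({
                "time_h": grid, "species": species, "replicate": run, "value": values,
            }))
        datasets.append(TimeSeriesDataset(pd.concat(frames, ignore_index=True)))
    return datasets


def simulate_noisy(
    p: ModelParameters,
    species: Sequence[str],
    grid: Sequence[float],
    noise: NoiseSpec = NoiseSpec(),
    y0: np.ndarray | None = None,
) -> TimeSeriesDataset:
    """Model samples with additive white noise, floored at zero.

    Simulates at ``p``, samples the requested species on ``grid``, and adds
    i.i.d. ``N(0, sigma^2)`` noise; negative values are clipped to 0 (the
    observables are concentrations).  Deterministic given ``noise.seed``.
    """
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(noise.seed)
    sim_grid = grid if grid[0] == 0.0 else np.concatenate([[0.0], grid])
    traj = simulate(p, None, sim_grid, y0 if y0 is not None else default_initial_state())
    rows = np.searchsorted(traj.times, grid)
    frames = []
    for s in species:
        clean = traj.state(SPECIES_TO_STATE[s])[rows]
        noisy = clean + rng.normal(0.0, noise.sigma, size=len(grid)) if noise.sigma > 0 else clean
        frames.append(pd.DataFrame({
            "time_h": grid, "species": s, "replicate": 0,
            "value": np.clip(noisy, 0.0, None),
        }))
    return TimeSeriesDataset(pd.concat(frames, ignore_index=True))
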