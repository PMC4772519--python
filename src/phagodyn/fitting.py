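"""Least-squares estimation of model parameters from replicated time series.

The objective is the box-constrained sum of squared residuals

    F(x) = sum_i r_i^2,   r_i = w_s * (y~_i - f(t_i, x)),   l <= x <= u,

stacked over every record of every dataset, where ``f`` is the simulated
concentration of the record's species and ``w_s`` a per-species weight.  By
default ``w_s = 1 / std(observed values of species s)`` so histamine levels
and cell counts contribute on comparable scales.  Minimization is delegated
to the discrete-selection LM global optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dslm import LMOptions, OptResult, dslm_minimize
from .parameters import PARAM_NAMES, ModelParameters
from .simulate import default_initial_state, simulate

__all__ = [
    "SPECIES",
    "SPECIES_TO_STATE",
    "TimeSeriesDataset",
    "FitProblem",
    "default_bounds",
    "residuals",
    "fit",
]

#: Observable species and the model state each one is matched against.
SPECIES_TO_STATE: dict[str, str] = {
    "residual_histamine": "C_rh",
    "pmn": "C_pmn",
    "mphi": "C_mp",
}
SPECIES: tuple[str, ...] = tuple(SPECIES_TO_STATE)

_COLUMNS = ("time_h", "species", "replicate", "value")


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Replicated observations: records of (time_h, species, replicate, value)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        bad = set(self.frame["species"]) - set(SPECIES)
        if bad:
            raise ValueError(f"unknown species: {sorted(bad)}; valid: {SPECIES}")
        if len(self.frame) == 0:
            raise ValueError("dataset has no records")
        if (self.frame["value"] < 0).any():
            raise ValueError("observed values must be >= 0")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[float, str, object, float]]
    ) -> "TimeSeriesDataset":
        return cls(pd.DataFrame(records, columns=list(_COLUMNS)))

    @classmethod
    def from_arrays(
        cls, times: Sequence[float], values: Sequence[float],
        species: str, replicate: object = 0,
    ) -> "TimeSeriesDataset":
        return cls(pd.DataFrame({
            "time_h": np.asarray(times, dtype=float),
            "species": species,
            "replicate": replicate,
            "value": np.asarray(values, dtype=float),
        }))

    def species_present(self) -> list[str]:
        return sorted(set(self.frame["species"]))

    def times(self) -> np.ndarray:
        """Sorted union of observation times over all species."""
        return np.unique(self.frame["time_h"].to_numpy(dtype=float))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TimeSeriesDataset":
        return cls(pd.read_csv(path))


def default_bounds(horizon: float = 16.0) -> tuple[np.ndarray, np.ndarray]:
    """Default estimation box: rates in [0, 20], damping in [0, 0.99],
    onset time within the observation horizon."""
    lower = np.zeros(len(PARAM_NAMES))
    upper = np.full(len(PARAM_NAMES), 20.0)
    upper[PARAM_NAMES.index("beta")] = 0.99
    upper[PARAM_NAMES.index("t1")] = horizon
    return lower, upper


@dataclass
class FitProblem:
    """A parameter-estimation problem: data, box, free parameters, weights.

    ``free`` names the parameters being estimated (default: all 22); the
    remaining parameters are pinned at ``base_params``.  ``weights`` maps
    species to positive scale factors; unspecified species get
    ``1 / std(observations)`` (or 1 when the spread is zero).
    """

    datasets: list[TimeSeriesDataset]
    base_params: ModelParameters
    lower: np.ndarray = None  # type: ignore[assignment]
    upper: np.ndarray = None  # type: ignore[assignment]
    free: Sequence[str] = PARAM_NAMES
    weights: dict[str, float] = field(default_factory=dict)
    y0: np.ndarray = field(default_factory=default_initial_state)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("need at least one dataset")
        if self.lower is None or self.upper is None:
            horizon = max(float(ds.frame["time_h"].max()) for ds in self.datasets)
            lo, up = default_bounds(horizon)
            self.lower = lo if self.lower is None else np.asarray(self.lower, float)
            self.upper = up if self.upper is None else np.asarray(self.upper, float)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != (len(PARAM_NAMES),) or self.upper.shape != (len(PARAM_NAMES),):
            raise ValueError(f"bounds must be 22-vectors in PARAM_NAMES order")
        if np.any(self.lower > self.upper):
            raise ValueError("need lower <= upper elementwise")
        unknown = set(self.free) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")
        bad_w = {s: w for s, w in self.weights.items() if w <= 0}
        if bad_w:
            raise ValueError(f"weights must be > 0, got {bad_w}")
        self._free_idx = np.array([PARAM_NAMES.index(n) for n in self.free], dtype=int)
        self._plan = None  # lazy per-dataset evaluation plan (hot-loop cache)
        self._weights = dict(self.weights)
        for ds in self.datasets:
            for s in ds.species_present():
                if s not in self._weights:
                    vals = np.concatenate([
                        d.frame.loc[d.frame["species"] == s, "value"].to_numpy(float)
                        for d in self.datasets if s in d.species_present()
                    ])
                    sd = float(vals.std())
                    self._weights[s] = 1.0 / sd if sd > 0 else 1.0

    # -- parameter-vector plumbing -----------------------------------------

    @property
    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lower[self._free_idx], self.upper[self._free_idx]

    def params_from_free(self, x_free: Sequence[float]) -> ModelParameters:
        full = self.base_params.to_array()
        full[self._free_idx] = np.asarray(x_free, dtype=float)
        return ModelParameters.from_array(full)

    def free_from_params(self, p: ModelParameters) -> np.ndarray:
        return p.to_array()[self._free_idx]

    def species_weight(self, species: str) -> float:
        return self._weights[species]

    def _evaluation_plan(self):
        """Per-dataset arrays extracted once, so the residual hot loop never
        touches pandas: (sim grid, [(row indices, observed values, weight)])."""
        if self._plan is None:
            plan = []
            for ds in self.datasets:
                t_union = ds.times()
                grid = t_union if t_union[0] == 0.0 else np.concatenate([[0.0], t_union])
                blocks = []
                for s in ds.species_present():
                    sub = ds.frame[ds.frame["species"] == s]
                    t_obs = sub["time_h"].to_numpy(float)
                    rows = np.searchsorted(grid, t_obs)
                    blocks.append((
                        SPECIES_TO_STATE[s], rows,
                        sub["value"].to_numpy(float), self.species_weight(s),
                    ))
                plan.append((grid, blocks))
            self._plan = plan
        return self._plan


def residuals(x_free: Sequence[float], prob: FitProblem) -> np.ndarray:
    """Stacked weighted residuals ``w_s (observed - simulated)``.

    Each dataset is simulated once on the union of its observation times
    (model output is sampled, never interpolated); records from all datasets
    are concatenated, so duplicating a dataset exactly doubles F.  Raises if
    ``x_free`` leaves the box or the simulation fails.
    """
    x_free = np.asarray(x_free, dtype=float)
    lo, up = prob.free_bounds
    if np.any(x_free < lo - 1e-12) or np.any(x_free > up + 1e-12):
        raise ValueError("parameter vector outside the feasible box")
    p = prob.params_from_free(x_free)
    out: list[np.ndarray] = []
    for grid, blocks in prob._evaluation_plan():
        traj = simulate(p, None, grid, prob.y0)
        for state_name, rows, values, w in blocks:
            sim = traj.state(state_name)[rows]
            out.append(w * (values - sim))
    return np.concatenate(out)


def fit(
    prob: FitProblem,
    opts: LMOptions | None = None,
    seed: int | None = None,
    n_cells: int = 20,
    max_outer: int = 100,
    tol: float = 1e-9,
    x0: Sequence[float] | None = None,
) -> OptResult:
    """Estimate the free parameters by DSLM; returns the optimizer result.

    ``result.x_best`` is the free-parameter vector (use
    ``prob.params_from_free`` to embed it in a full parameter set);
    ``result.score_trace`` is non-increasing across outer sweeps.
    """
    res = dslm_minimize(
        lambda x: residuals(x, prob),
        prob.free_bounds,
        n_cells=n_cells,
        opts=opts,
        seed=seed,
        max_outer=max_outer,
        tol=tol,
        x0=x0,
    )
    return res
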