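"""Multimodal benchmark functions and the optimizer assessment harness.

Two standard global-optimization test functions are provided:

- Rastrigin: ``F(x) = 10 d + sum(x_i^2 - 10 cos(2 pi x_i))`` on
  ``[-5.12, 5.12]^d``; global minimum 0 at the origin.
- Michalewicz: ``F(x) = -sum sin(x_i) sin^{2m}(i x_i^2 / pi)`` on
  ``[0, pi]^d`` with steepness ``m`` (default 10) and the index ``i``
  running from 1; it has d! local minima.

Because the optimizer core is a least-squares solver, each benchmark is also
exposed in an exact sum-of-squares form with an analytic Jacobian:

- Rastrigin: ``x_i^2 - 10 cos(2 pi x_i) + 10 = x_i^2 + 20 sin^2(pi x_i)``,
  so the smooth residuals ``(x_i, sqrt(20) sin(pi x_i))`` satisfy
  ``||r||^2 = F(x)`` exactly.
- Michalewicz: each term ``s_i = sin(x_i) sin^{2m}(i x_i^2/pi)`` lies in
  ``[0, 1]`` on the domain, so ``r_i = sqrt(1 - s_i)`` gives
  ``||r||^2 = d + F(x)`` (a constant offset that does not move the argmin).

Reported scores are always the plain benchmark value at the returned point,
never the shifted residual norm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .dslm import LMOptions, dslm_minimize, lm_minimize

__all__ = [
    "rastrigin",
    "michalewicz",
    "BenchmarkProblem",
    "BenchmarkReport",
    "multistart_lm",
    "grid_polish_minimum",
    "run_benchmark",
]

OPTIMIZER_NAMES = ("dslm", "lm_multistart", "grid_polish", "external")

#: Coordinates of the known 10-d Michalewicz (m=10) global minimum, to the
#: precision usually quoted; its value is about -9.66015.
MICHALEWICZ_ARGMIN_10D = (2.2, 1.57, 1.29, 1.92, 1.72, 1.57, 1.45, 1.76, 1.66, 1.57)

#: Start count for uniform-random multistart on the 5-d Michalewicz function.
#: The measured per-start probability of landing every coordinate in its
#: globally optimal valley is ~9e-5; this count bounds the miss probability
#: near 1e-3.
MICHALEWICZ_5D_STARTS = 80_000

_RESIDUAL_FLOOR = 1e-14  # keeps sqrt(1 - s) differentiable when s -> 1


def rastrigin(x: Sequence[float]) -> float:
    """Rastrigin test function; >= 0 everywhere, 0 only at the origin."""
    x = np.asarray(x, dtype=float)
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def michalewicz(x: Sequence[float], m: int = 10) -> float:
    """Michalewicz test function on [0, pi]^d with steepness m."""
    x = np.asarray(x, dtype=float)
    i = np.arange(1, x.size + 1)
    return float(-np.sum(np.sin(x) * np.sin(i * x * x / np.pi) ** (2 * m)))


def _rastrigin_residuals(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.concatenate([x, math.sqrt(20.0) * np.sin(np.pi * x)])


def _rastrigin_jac(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    d = x.size
    J = np.zeros((2 * d, d))
    J[:d, :] = np.eye(d)
    J[d:, :] = np.diag(math.sqrt(20.0) * np.pi * np.cos(np.pi * x))
    return J


def _michalewicz_terms(x: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-dimension terms s_i and their derivatives ds_i/dx_i."""
    i = np.arange(1, x.size + 1)
    u = i * x * x / np.pi
    sin_u = np.sin(u)
    s = np.sin(x) * sin_u ** (2 * m)
    ds = (
        np.cos(x) * sin_u ** (2 * m)
        + np.sin(x) * 2 * m * sin_u ** (2 * m - 1) * np.cos(u) * (2.0 * i * x / np.pi)
    )
    return s, ds


def _michalewicz_residuals(x: np.ndarray, m: int) -> np.ndarray:
    s, _ = _michalewicz_terms(np.asarray(x, dtype=float), m)
    return np.sqrt(np.clip(1.0 - s, _RESIDUAL_FLOOR, None))


def _michalewicz_jac(x: np.ndarray, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    s, ds = _michalewicz_terms(x, m)
    r = np.sqrt(np.clip(1.0 - s, _RESIDUAL_FLOOR, None))
    return np.diag(-ds / (2.0 * r))


@dataclass(frozen=True)
class BenchmarkProblem:
    """A benchmark instance: function name, dimension, and (for Michalewicz)
    the steepness ``m``."""

    name: str
    d: int
    m: int = 10

    def __post_init__(self) -> None:
        if self.name not in ("rastrigin", "michalewicz"):
            raise ValueError(f"unknown benchmark {self.name!r}")
        if self.d < 1:
            raise ValueError("dimension must be >= 1")

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.name == "rastrigin":
            return -5.12 * np.ones(self.d), 5.12 * np.ones(self.d)
        return np.zeros(self.d), np.pi * np.ones(self.d)

    def value(self, x: Sequence[float]) -> float:
        if self.name == "rastrigin":
            return rastrigin(x)
        return michalewicz(x, self.m)

    @property
    def residual_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.name == "rastrigin":
            return _rastrigin_residuals
        m = self.m
        return lambda x: _michalewicz_residuals(x, m)

    @property
    def jac_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        if self.name == "rastrigin":
            return _rastrigin_jac
        m = self.m
        return lambda x: _michalewicz_jac(x, m)


@dataclass
class BenchmarkReport:
    """Seeded repeat runs of one optimizer on one problem, with summaries."""

    problem: BenchmarkProblem
    optimizer: str
    runs: list[tuple[int, float, int]] = field(default_factory=list)  # (seed, score, iterations)

    def summary(self) -> dict[str, float]:
        scores = np.array([s for _, s, _ in self.runs])
        iters = np.array([it for _, _, it in self.runs])
        return {
            "mean_score": float(scores.mean()),
            "std_score": float(scores.std(ddof=1)) if len(scores) > 1 else 0.0,
            "mean_iterations": float(iters.mean()),
            "std_iterations": float(iters.std(ddof=1)) if len(iters) > 1 else 0.0,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "problem": self.problem.name,
                "d": self.problem.d,
                "optimizer": self.optimizer,
                "seed": [s for s, _, _ in self.runs],
                "score": [sc for _, sc, _ in self.runs],
                "iterations": [it for _, _, it in self.runs],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def multistart_lm(
    prob: BenchmarkProblem,
    n_starts: int,
    seed: int | None = None,
    opts: LMOptions | None = None,
) -> tuple[np.ndarray, float]:
    """Plain multi-start local search: LM from uniform random points.

    Serves as an independent global baseline (no discretization, no marking).
    Returns the best point and its benchmark value.
    """
    if n_starts < 1:
        raise ValueError("need n_starts >= 1")
    lower, upper = prob.bounds
    rng = np.random.default_rng(seed)
    best_x, best_f = None, np.inf
    for _ in range(n_starts):
        x0 = lower + rng.uniform(size=prob.d) * (upper - lower)
        res = lm_minimize(prob.residual_fn, x0, (lower, upper), opts, jac=prob.jac_fn)
        f = prob.value(res.x_best)
        if f < best_f:
            best_x, best_f = res.x_best, f
    return best_x, best_f


def grid_polish_minimum(
    prob: BenchmarkProblem,
    step: float = 0.005,
    opts: LMOptions | None = None,
    chunk: int = 256,
) -> tuple[np.ndarray, float]:
    """Deterministic oracle: dense grid search plus one LM polish.

    Enumerates the full tensor grid with spacing ``step`` (evaluated in
    chunks of rows to bound memory; practical for d <= 2), polishes the best
    grid point with LM, and returns the better of the two.
    """
    if prob.d > 2:
        raise ValueError("dense grid enumeration is limited to d <= 2")
    lower, upper = prob.bounds
    axes = [np.arange(lower[j], upper[j] + step / 2, step) for j in range(prob.d)]
    best_x, best_f = None, np.inf
    if prob.d == 1:
        vals = _vector_values(prob, axes[0][:, None])
        k = int(np.argmin(vals))
        best_x, best_f = axes[0][k : k + 1].copy(), float(vals[k])
    else:
        for start in range(0, len(axes[0]), chunk):
            x1 = axes[0][start : start + chunk]
            X1, X2 = np.meshgrid(x1, axes[1], indexing="ij")
            pts = np.column_stack([X1.ravel(), X2.ravel()])
            vals = _vector_values(prob, pts)
            k = int(np.argmin(vals))
            if vals[k] < best_f:
                best_x, best_f = pts[k].copy(), float(vals[k])
    res = lm_minimize(prob.residual_fn, best_x, prob.bounds, opts, jac=prob.jac_fn)
    f_polished = prob.value(res.x_best)
    if f_polished < best_f:
        return res.x_best, f_polished
    return best_x, best_f


def _vector_values(prob: BenchmarkProblem, pts: np.ndarray) -> np.ndarray:
    """Benchmark values for a (n, d) array of points, vectorized."""
    if prob.name == "rastrigin":
        return 10.0 * pts.shape[1] + np.sum(
            pts * pts - 10.0 * np.cos(2.0 * np.pi * pts), axis=1
        )
    i = np.arange(1, pts.shape[1] + 1)
    return -np.sum(np.sin(pts) * np.sin(i * pts * pts / np.pi) ** (2 * prob.m), axis=1)


def run_benchmark(
    prob: BenchmarkProblem,
    optimizer: str = "dslm",
    n_runs: int = 10,
    seeds: Sequence[int] | None = None,
    n_cells: int = 20,
    opts: LMOptions | None = None,
    n_starts: int = 100,
    grid_step: float = 0.005,
    external: Callable[[BenchmarkProblem, int], tuple[np.ndarray, float, int]] | None = None,
) -> BenchmarkReport:
    """Run one optimizer ``n_runs`` times and summarize scores/iterations.

    Initial guesses are uniform in the box, controlled by per-run seeds
    (default ``1..n_runs``).  For DSLM the recorded iteration count is the
    number of outer sweeps; for multi-start it is the number of starts, and
    for the deterministic grid oracle it is 1.  ``external`` plugs in a
    third-party optimizer for comparison tables.
    """
    if optimizer not in OPTIMIZER_NAMES:
        raise ValueError(f"unknown optimizer {optimizer!r}; valid: {OPTIMIZER_NAMES}")
    seeds = list(range(1, n_runs + 1)) if seeds is None else list(seeds)
    report = BenchmarkReport(problem=prob, optimizer=optimizer)
    for s in seeds:
        if optimizer == "dslm":
            res = dslm_minimize(
                prob.residual_fn, prob.bounds, n_cells=n_cells, opts=opts,
                seed=s, jac=prob.jac_fn,
            )
            score, iters = prob.value(res.x_best), res.outer_iterations
        elif optimizer == "lm_multistart":
            _, score = multistart_lm(prob, n_starts, seed=s, opts=opts)
            iters = n_starts
        elif optimizer == "grid_polish":
            _, score = grid_polish_minimum(prob, step=grid_step, opts=opts)
            iters = 1
        else:
            if external is None:
                raise ValueError("optimizer 'external' requires the external callable")
            _, score, iters = external(prob, s)
        report.runs.append((s, float(score), int(iters)))
    return report
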