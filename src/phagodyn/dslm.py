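"""Levenberg-Marquardt local solver and the Discrete Selection global strategy.

The local solver minimizes ``F(x) = ||r(x)||^2`` subject to box constraints
by damped Gauss-Newton steps ``(J^T J + mu I) d = -J^T r`` with the classic
gain-ratio damping update (shrink ``mu`` on good steps, multiply by a doubling
factor ``nu`` on rejected ones).  Trial points are projected orthogonally
onto the box.

Discrete Selection LM (DSLM) wraps the local solver into a global strategy:
each free parameter's interval is split into ``N`` uniform cells; the
optimizer sweeps the parameters one at a time, launching a full LM run from
every cell midpoint whose cell is still unmarked, and marking all cells that
the launch traversed in that coordinate (from the start cell to the cell of
the converged coordinate).  Marking only prunes redundant launches — it never
changes which minimizer a launch converges to, so the discretization does not
limit the accuracy of the result.  After each full sweep the best point is
polished by one more LM run.  The number of LM launches per sweep is at most
``sum_j N_j + 1`` (linear, not exponential, in the number of parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "LMOptions",
    "DiscretizationGrid",
    "OptResult",
    "lm_minimize",
    "select_dimension",
    "dslm_minimize",
]

ResidualFn = Callable[[np.ndarray], np.ndarray]
JacFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class LMOptions:
    """Tuning knobs of the local LM solver.

    ``tau`` scales the initial damping (``mu0 = tau * max diag(J^T J)``),
    ``nu`` is the growth factor applied to ``mu`` after a rejected step,
    ``fd_rel`` the relative forward-difference step used when no analytic
    Jacobian is supplied.
    """

    tau: float = 1e-3
    nu: float = 2.0
    max_iter: int = 200
    gtol: float = 1e-8
    xtol: float = 1e-10
    fd_rel: float = 1e-6

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.nu <= 1:
            raise ValueError("need tau > 0 and nu > 1")
        if self.gtol <= 0 or self.xtol <= 0 or self.fd_rel <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class OptResult:
    """Outcome of a local or global minimization."""

    x_best: np.ndarray
    f_best: float
    outer_iterations: int
    score_trace: list[float]
    lm_calls: int = 1
    seed: int | None = None
    converged: bool = True
    lm_calls_per_sweep: list[int] = field(default_factory=list)


class DiscretizationGrid:
    """Per-parameter uniform cell partition of the box, with marks.

    Dimension ``j`` of ``[l_j, u_j]`` is covered by ``N_j`` contiguous cells;
    ``marks[j][k]`` records that cell ``k`` has already been visited by an LM
    launch during the current sweep.  Zero-width (fixed) dimensions get no
    cells.
    """

    def __init__(self, lower: np.ndarray, upper: np.ndarray, n_cells: int | Sequence[int]):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        p = len(self.lower)
        n = np.full(p, n_cells, dtype=int) if np.isscalar(n_cells) else np.asarray(n_cells, int)
        if np.any(n < 1):
            raise ValueError("need at least one cell per dimension")
        self.n_cells = np.where(self.upper > self.lower, n, 0)
        self.edges = [
            np.linspace(self.lower[j], self.upper[j], self.n_cells[j] + 1)
            if self.n_cells[j] else np.array([self.lower[j]])
            for j in range(p)
        ]
        self.marks = [np.zeros(self.n_cells[j], dtype=bool) for j in range(p)]

    def cell_index(self, j: int, value: float) -> int:
        """Cell of dimension ``j`` containing ``value`` (clipped to the box)."""
        if self.n_cells[j] == 0:
            raise ValueError(f"dimension {j} is fixed (zero width)")
        k = int(np.searchsorted(self.edges[j], value, side="right")) - 1
        return min(max(k, 0), self.n_cells[j] - 1)

    def midpoint(self, j: int, k: int) -> float:
        return 0.5 * (self.edges[j][k] + self.edges[j][k + 1])

    def mark_range(self, j: int, k1: int, k2: int) -> None:
        lo, hi = min(k1, k2), max(k1, k2)
        self.marks[j][lo : hi + 1] = True

    def fraction_marked(self) -> float:
        total = int(self.n_cells.sum())
        if total == 0:
            return 1.0
        return sum(int(m.sum()) for m in self.marks) / total


def _fd_jacobian(
    residual_fn: ResidualFn,
    x: np.ndarray,
    r: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    fd_rel: float,
) -> np.ndarray:
    """Forward-difference Jacobian of the residual, respecting the box."""
    p = len(x)
    J = np.empty((len(r), p))
    for j in range(p):
        h = fd_rel * max(abs(x[j]), 1.0)
        if x[j] + h > upper[j]:
            h = -h  # backward difference at the upper bound
        xj = x.copy()
        xj[j] += h
        J[:, j] = (np.asarray(residual_fn(xj), dtype=float) - r) / h
    return J


def _safe_residual(residual_fn: ResidualFn, x: np.ndarray) -> tuple[np.ndarray | None, float]:
    """Evaluate residuals, mapping failures / non-finite values to F = inf."""
    try:
        r = np.asarray(residual_fn(x), dtype=float)
    except (ValueError, RuntimeError, FloatingPointError, ZeroDivisionError):
        return None, np.inf
    if not np.all(np.isfinite(r)):
        return None, np.inf
    return r, float(r @ r)


def lm_minimize(
    residual_fn: ResidualFn,
    x0: Sequence[float],
    bounds: tuple[Sequence[float], Sequence[float]],
    opts: LMOptions | None = None,
    jac: JacFn | None = None,
) -> OptResult:
    """Box-constrained damped Gauss-Newton (Levenberg-Marquardt) descent.

    Starting from ``x0`` (projected onto the box), solves
    ``(J^T J + mu I) d = -J^T r`` for the step, accepts it only when the sum
    of squares decreases, and adapts ``mu`` by the gain ratio between actual
    and predicted decrease.  Guarantees ``F(x_out) <= F(x0)``; the score
    trace records accepted values only and is therefore non-increasing.
    Singular normal equations are handled by raising ``mu``, never by
    aborting.
    """
    opts = opts or LMOptions()
    lower = np.asarray(bounds[0], dtype=float)
    upper = np.asarray(bounds[1], dtype=float)
    x = np.clip(np.asarray(x0, dtype=float), lower, upper)

    r = np.asarray(residual_fn(x), dtype=float)
    if not np.all(np.isfinite(r)):
        raise ValueError("residual function returned non-finite values at x0")
    F = float(r @ r)
    trace = [F]

    def jacobian(xc: np.ndarray, rc: np.ndarray) -> np.ndarray:
        if jac is not None:
            return np.asarray(jac(xc), dtype=float)
        return _fd_jacobian(residual_fn, xc, rc, lower, upper, opts.fd_rel)

    J = jacobian(x, r)
    A = J.T @ J
    g = J.T @ r  # gradient of F/2
    mu = opts.tau * max(float(np.max(np.diag(A))), np.finfo(float).tiny)
    nu = opts.nu
    n_iter = 0
    converged = False

    while n_iter < opts.max_iter:
        if float(np.max(np.abs(g))) < opts.gtol:
            converged = True
            break
        n_iter += 1
        try:
            d = np.linalg.solve(A + mu * np.eye(len(x)), -g)
        except np.linalg.LinAlgError:
            mu *= nu
            nu *= opts.nu
            continue
        if not np.all(np.isfinite(d)):
            mu *= nu
            nu *= opts.nu
            continue
        x_new = np.clip(x + d, lower, upper)
        step = x_new - x
        if np.linalg.norm(step) < opts.xtol * (np.linalg.norm(x) + opts.xtol):
            converged = True
            break
        r_new, F_new = _safe_residual(residual_fn, x_new)
        if F_new < F:
            predicted = 0.5 * float(step @ (mu * step - g))  # > 0 for unclipped steps
            rho = (0.5 * (F - F_new)) / predicted if predicted > 0 else 1.0
            x, r, F = x_new, r_new, F_new
            trace.append(F)
            J = jacobian(x, r)
            A = J.T @ J
            g = J.T @ r
            mu *= max(1.0 / 3.0, 1.0 - (2.0 * rho - 1.0) ** 3)
            nu = opts.nu
            if F == 0.0:
                converged = True
                break
        else:
            mu *= nu
            nu *= opts.nu
            if mu > 1e16:  # hopeless direction: damping saturated
                break

    return OptResult(
        x_best=x, f_best=F, outer_iterations=n_iter,
        score_trace=trace, lm_calls=1, converged=converged,
    )


def select_dimension(
    j: int,
    x: np.ndarray,
    grid: DiscretizationGrid,
    residual_fn: ResidualFn,
    bounds: tuple[np.ndarray, np.ndarray],
    opts: LMOptions | None = None,
    jac: JacFn | None = None,
    f_x: float | None = None,
) -> tuple[np.ndarray, float, int]:
    """One discrete-selection pass over dimension ``j``.

    For every still-unmarked cell of dimension ``j``, launch a full LM run
    from the incumbent with ``x_j`` replaced by the cell midpoint, then mark
    all cells of dimension ``j`` between the launch cell and the cell of the
    converged coordinate (inclusive).  Returns the best of the incumbent and
    all launches (never worse than the incumbent), its score, and the number
    of LM launches made.  Already-marked cells cost nothing.
    """
    if f_x is None:
        r, f_x = _safe_residual(residual_fn, x)
        if r is None:
            raise ValueError("residual function failed at the incumbent")
    best_x, best_f = x, f_x
    lm_calls = 0
    for k in range(grid.n_cells[j]):
        if grid.marks[j][k]:
            continue
        cand = x.copy()
        cand[j] = grid.midpoint(j, k)
        res = lm_minimize(residual_fn, cand, bounds, opts, jac)
        lm_calls += 1
        grid.mark_range(j, k, grid.cell_index(j, res.x_best[j]))
        if res.f_best < best_f:
            best_x, best_f = res.x_best, res.f_best
    return best_x, best_f, lm_calls


def dslm_minimize(
    residual_fn: ResidualFn,
    bounds: tuple[Sequence[float], Sequence[float]],
    n_cells: int = 20,
    opts: LMOptions | None = None,
    seed: int | None = None,
    max_outer: int = 100,
    tol: float = 1e-9,
    jac: JacFn | None = None,
    x0: Sequence[float] | None = None,
) -> OptResult:
    """Discrete Selection Levenberg-Marquardt global minimization.

    Draws the initial point uniformly in the box (from ``seed``), then
    repeats sweeps until the score stalls (``|dF| <= tol * (1 + |F|)``) or
    ``max_outer`` sweeps have run: each sweep resets the discretization
    marks, applies :func:`select_dimension` to every free parameter in index
    order, and finishes with one full LM polish from the sweep's best point.
    The returned score trace (one entry per sweep, plus the initial score)
    is non-increasing by construction.  Dimensions with ``l_j == u_j`` are
    held fixed.
    """
    opts = opts or LMOptions()
    lower = np.asarray(bounds[0], dtype=float)
    upper = np.asarray(bounds[1], dtype=float)
    if lower.shape != upper.shape or lower.ndim != 1:
        raise ValueError("bounds must be two equal-length 1-d arrays")
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("bounds must be finite")
    if np.any(lower > upper):
        raise ValueError("need lower <= upper elementwise")
    free = np.flatnonzero(upper > lower)

    if x0 is None:
        rng = np.random.default_rng(seed)
        x = lower + rng.uniform(size=len(lower)) * (upper - lower)
    else:
        x = np.clip(np.asarray(x0, dtype=float), lower, upper)

    r0, F = _safe_residual(residual_fn, x)
    if r0 is None:
        raise ValueError("residual function failed at the initial point")
    trace = [F]
    total_lm = 0
    calls_per_sweep: list[int] = []
    converged = False
    outer = 0

    if len(free) == 0:  # fully pinned box: nothing to optimize
        return OptResult(x, F, 0, trace, 0, seed, True, [])

    for outer in range(1, max_outer + 1):
        grid = DiscretizationGrid(lower, upper, n_cells)
        sweep_calls = 0
        for j in free:
            x, F, calls = select_dimension(
                j, x, grid, residual_fn, (lower, upper), opts, jac, f_x=F
            )
            sweep_calls += calls
        polish = lm_minimize(residual_fn, x, (lower, upper), opts, jac)
        sweep_calls += 1
        if polish.f_best < F:
            x, F = polish.x_best, polish.f_best
        total_lm += sweep_calls
        calls_per_sweep.append(sweep_calls)
        trace.append(F)
        logger.info(
            "dslm outer=%d F=%.6g lm_calls=%d marked=%.2f",
            outer, F, sweep_calls, grid.fraction_marked(),
        )
        if abs(trace[-2] - F) <= tol * (1.0 + abs(F)):
            converged = True
            break

    return OptResult(
        x_best=x, f_best=F, outer_iterations=outer, score_trace=trace,
        lm_calls=total_lm, seed=seed, converged=converged,
        lm_calls_per_sweep=calls_per_sweep,
    )
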