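"""Right-hand sides of the phagocyte-transmigration kinetic model.

The model tracks eight concentrations (all in arbitrary units):

==========  ===========================================================
index/name  meaning
==========  ===========================================================
0  C_rh     residual histamine (granules stored in mast cells)
1  C_h      free histamine
2  C_hr     active H1/H2 histamine receptors
3  C_s      P/E selectins on the endothelium
4  C_pmnp   capillary permeability for PMN
5  C_mpp    capillary permeability for MPhi
6  C_pmn    total recruited PMN
7  C_mp     total recruited MPhi
==========  ===========================================================

Residual histamine decays (degranulation) and is replenished by a
damped-harmonic-oscillator mast-cell source that switches on at time ``t1``.
Released histamine drives receptor and selectin activation through saturating
(hyperbolic) production terms; the receptor x selectin product drives
capillary permeability, which accumulates into the recruited phagocyte
totals.  Five knockout indicator functions (values in [0, 1]) model
mast-cell deficiency and pharmacological blocking of receptors/selectins.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .parameters import ModelParameters

__all__ = [
    "STATE_NAMES",
    "N_STATES",
    "StepFunction",
    "PerturbationSchedule",
    "mast_cell_source",
    "derivatives",
    "make_rhs",
]

STATE_NAMES: tuple[str, ...] = (
    "C_rh", "C_h", "C_hr", "C_s", "C_pmnp", "C_mpp", "C_pmn", "C_mp",
)
N_STATES = len(STATE_NAMES)


@dataclass(frozen=True)
class StepFunction:
    """Piecewise-constant function of time, right-continuous at breakpoints.

    ``levels`` has one more entry than ``breakpoints``; on the interval
    ``[breakpoints[i-1], breakpoints[i])`` the function takes ``levels[i]``.
    The default is the constant function 1 (no knockout).
    """

    breakpoints: tuple[float, ...] = ()
    levels: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.breakpoints) + 1:
            raise ValueError("need len(levels) == len(breakpoints) + 1")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(not 0.0 <= lv <= 1.0 for lv in self.levels):
            raise ValueError("levels must lie in [0, 1]")

    def __call__(self, t: float) -> float:
        # right-continuous: at a breakpoint the new level already applies
        return self.levels[bisect.bisect_right(self.breakpoints, t)]

    @classmethod
    def constant(cls, level: float = 1.0) -> "StepFunction":
        return cls((), (float(level),))

    @classmethod
    def step(cls, at: float, level: float, before: float = 1.0) -> "StepFunction":
        """Level ``before`` until ``at``, then ``level`` (right-continuous)."""
        return cls((float(at),), (float(before), float(level)))


_INDICATOR_NAMES = ("I_mc", "I_pmnhr", "I_mphr", "I_pmns", "I_mps")


@dataclass(frozen=True)
class PerturbationSchedule:
    """The five knockout indicators of the model.

    ``I_mc`` scales histamine release from mast cells (mast-cell deficiency),
    ``I_pmnhr``/``I_mphr`` gate the receptor contribution to PMN/MPhi
    permeability (H1/H2 antagonists), and ``I_pmns``/``I_mps`` gate the
    selectin contribution.  All default to the constant 1 (no perturbation).
    """

    I_mc: StepFunction = field(default_factory=StepFunction)
    I_pmnhr: StepFunction = field(default_factory=StepFunction)
    I_mphr: StepFunction = field(default_factory=StepFunction)
    I_pmns: StepFunction = field(default_factory=StepFunction)
    I_mps: StepFunction = field(default_factory=StepFunction)

    def levels_at(self, t: float) -> tuple[float, float, float, float, float]:
        return (self.I_mc(t), self.I_pmnhr(t), self.I_mphr(t),
                self.I_pmns(t), self.I_mps(t))

    def breakpoints(self) -> list[float]:
        """Sorted union of all indicator breakpoints."""
        pts: set[float] = set()
        for name in _INDICATOR_NAMES:
            pts.update(getattr(self, name).breakpoints)
        return sorted(pts)


def mast_cell_source(t: float, p: ModelParameters) -> float:
    """Rate at which the mast-cell source replenishes residual histamine.

    Zero before the onset time ``t1``; afterwards a decaying envelope
    ``A(t) = k_e0 * exp(-k_k1 (t - t1))`` plus a damped oscillation around it:

        U(t) = A(t) + A(t) exp(-beta (t - t1))
                      * cos(sqrt(1 - beta^2) * w0(t) * (t - t1)),
        w0(t) = k_w0 * exp(-k_k2 (t - t1)).

    The cosine phase is the literal product of the instantaneous frequency
    ``w0(t)`` with the elapsed time (a frequency-chirped waveform), not the
    integral of ``w0``; the two differ whenever ``k_k2 > 0``.

    Since ``|cos| <= 1``, ``0 <= U(t) <= 2 A(t)`` for all ``t >= t1``.
    """
    if not math.isfinite(t):
        raise ValueError(f"time must be finite, got {t!r}")
    if p.beta >= 1.0:
        raise ValueError("beta must be < 1 for a real oscillation frequency")
    if t < p.t1:
        return 0.0
    dt = t - p.t1
    a = p.k_e0 * math.exp(-p.k_k1 * dt)
    w0 = p.k_w0 * math.exp(-p.k_k2 * dt)
    return a + a * math.exp(-p.beta * dt) * math.cos(
        math.sqrt(1.0 - p.beta * p.beta) * w0 * dt
    )


def make_rhs(
    p: ModelParameters,
    indicator_levels: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0),
) -> Callable[[float, Sequence[float]], list[float]]:
    """Build a fast ``f(t, y)`` closure for a segment of constant indicators.

    The integrator restarts at every indicator breakpoint, so within a
    segment the five indicator levels are plain constants; binding them (and
    the parameters) to locals keeps the per-call cost low, which matters
    because fitting evaluates the model thousands of times.
    """
    i_mc, i_pmnhr, i_mphr, i_pmns, i_mps = (float(v) for v in indicator_levels)
    t1, k_e0, k_k1, beta = p.t1, p.k_e0, p.k_k1, p.beta
    k_w0, k_k2, k_rhch, k_hs = p.k_w0, p.k_k2, p.k_rhch, p.k_hs
    k_hchrb, k_hchrt, k_hrs = p.k_hchrb, p.k_hchrt, p.k_hrs
    k_hcsb, k_hcst, k_ss = p.k_hcsb, p.k_hcst, p.k_ss
    k_pmnipb, k_pmnipt, k_pmnps = p.k_pmnipb, p.k_pmnipt, p.k_pmnps
    k_mpipb, k_mpipt, k_mpps = p.k_mpipb, p.k_mpipt, p.k_mpps
    k_pmns, k_mps = p.k_pmns, p.k_mps
    sq = math.sqrt(1.0 - beta * beta)
    exp, cos = math.exp, math.cos
    gate_pmn = i_pmns * i_pmnhr
    gate_mp = i_mps * i_mphr

    def rhs(t: float, y: Sequence[float]) -> list[float]:
        c_rh, c_h, c_hr, c_s, c_pmnp, c_mpp, c_pmn, c_mp = y
        if t < t1:
            u = 0.0
        else:
            dt = t - t1
            a = k_e0 * exp(-k_k1 * dt)
            u = a + a * exp(-beta * dt) * cos(sq * k_w0 * exp(-k_k2 * dt) * dt)
        x_pmn = c_hr * c_s * gate_pmn
        x_mp = c_hr * c_s * gate_mp
        return [
            -k_rhch * c_rh + u,
            k_rhch * c_rh * i_mc - k_hs * c_h,
            k_hchrt * c_h / (k_hchrb + c_h) - k_hrs * c_hr,
            k_hcst * c_h / (k_hcsb + c_h) - k_ss * c_s,
            k_pmnipt * x_pmn / (k_pmnipb + x_pmn) - k_pmnps * c_pmnp,
            k_mpipt * x_mp / (k_mpipb + x_mp) - k_mpps * c_mpp,
            c_pmnp - k_pmns * c_pmn,
            c_mpp - k_mps * c_mp,
        ]

    return rhs


def derivatives(
    t: float,
    y: Sequence[float],
    p: ModelParameters,
    schedule: PerturbationSchedule | None = None,
) -> np.ndarray:
    """Time derivatives of the eight state variables at time ``t``.

    ``y`` is in STATE_NAMES order.  When ``schedule`` is None the unperturbed
    equations (all indicators 1) are evaluated; passing an all-ones schedule
    gives bitwise-identical results because both paths call the same closure.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        raise ValueError("state vector contains non-finite values")
    levels = (1.0,) * 5 if schedule is None else schedule.levels_at(t)
    return np.array(make_rhs(p, levels)(t, y), dtype=float)
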