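"""Model parameterization: the 22 rate/shape constants of the transmigration system.

The kinetic model has eight state variables (residual histamine, free
histamine, active H1/H2 receptors, P/E selectins, capillary permeability for
PMN and for MPhi, and the totals of recruited PMN and MPhi).  Its dynamics are
governed by 22 non-negative scalar constants, named here exactly as they
appear in flat key=value parameter files.  A packaged reference estimate
(``reference_parameters()``) carries the values obtained by fitting the model
to mouse implant measurements; it is the default parameter set throughout the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ModelParameters",
    "reference_parameters",
]

#: Canonical parameter ordering, used for all vector <-> parameter conversions.
PARAM_NAMES: tuple[str, ...] = (
    "t1",        # onset of the mast-cell source (h)
    "k_e0",      # initial amplitude of the source (a.u.)
    "k_k1",      # contraction rate of the source envelope (1/h)
    "beta",      # oscillator damping (dimensionless, in [0, 1))
    "k_w0",      # initial oscillation frequency (rad/h)
    "k_k2",      # contraction rate of the oscillation frequency (1/h)
    "k_rhch",    # residual-histamine decay = histamine release rate (1/h)
    "k_hs",      # histamine self-degradation rate (1/h)
    "k_hchrb",   # receptor-release hyperbolic half-saturation (a.u.)
    "k_hchrt",   # receptor-release hyperbolic ceiling (a.u./h)
    "k_hrs",     # receptor self-degradation rate (1/h)
    "k_hcsb",    # selectin-release hyperbolic half-saturation (a.u.)
    "k_hcst",    # selectin-release hyperbolic ceiling (a.u./h)
    "k_ss",      # selectin self-degradation rate (1/h)
    "k_pmnipb",  # PMN-permeability hyperbolic half-saturation (a.u.)
    "k_pmnipt",  # PMN-permeability hyperbolic ceiling (a.u./h)
    "k_pmnps",   # PMN-permeability decay rate (1/h)
    "k_mpipb",   # MPhi-permeability hyperbolic half-saturation (a.u.)
    "k_mpipt",   # MPhi-permeability hyperbolic ceiling (a.u./h)
    "k_mpps",    # MPhi-permeability decay rate (1/h)
    "k_pmns",    # PMN self-degradation rate (1/h)
    "k_mps",     # MPhi self-degradation rate (1/h)
)

# Hyperbolic half-saturation constants appear in denominators and must stay
# strictly positive.
_POSITIVE_DENOMS = ("k_hchrb", "k_hcsb", "k_pmnipb", "k_mpipb")


@dataclass(frozen=True)
class ModelParameters:
    """The 22 named constants of the transmigration model.

    All values are in arbitrary units per hour (rates) or arbitrary units
    (amplitudes and half-saturations); ``t1`` is in hours.  Invariants: every
    field is non-negative, ``0 <= beta < 1`` so the damped-oscillator
    frequency factor ``sqrt(1 - beta**2)`` is real, and the four hyperbolic
    half-saturation constants are strictly positive.
    """

    t1: float
    k_e0: float
    k_k1: float
    beta: float
    k_w0: float
    k_k2: float
    k_rhch: float
    k_hs: float
    k_hchrb: float
    k_hchrt: float
    k_hrs: float
    k_hcsb: float
    k_hcst: float
    k_ss: float
    k_pmnipb: float
    k_pmnipt: float
    k_pmnps: float
    k_mpipb: float
    k_mpipt: float
    k_mpps: float
    k_pmns: float
    k_mps: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v!r}")
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must lie in [0, 1), got {self.beta!r}")
        for name in _POSITIVE_DENOMS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")

    # -- vector conversions -------------------------------------------------

    def to_array(self) -> np.ndarray:
        """Return the parameters as a length-22 vector in PARAM_NAMES order."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, x: Iterable[float]) -> "ModelParameters":
        x = np.asarray(list(x), dtype=float)
        if x.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got shape {x.shape}")
        return cls(**dict(zip(PARAM_NAMES, map(float, x))))

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in PARAM_NAMES}

    def with_updates(self, **updates: float) -> "ModelParameters":
        return replace(self, **updates)

    # -- flat key=value file I/O -------------------------------------------

    def to_file(self, path: str | Path) -> None:
        """Write a flat ``name = value`` file using the canonical names."""
        lines = [f"{n} = {getattr(self, n):.10g}" for n in PARAM_NAMES]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParameters":
        return cls.from_mapping(_parse_kv(Path(path).read_text()))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise ValueError(f"missing parameter name(s): {sorted(missing)}")
        return cls(**{n: float(mapping[n]) for n in PARAM_NAMES})


def _parse_kv(text: str) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'name = value', got {raw!r}")
        name, value = (part.strip() for part in line.split("=", 1))
        out[name] = float(value)
    return out


def reference_parameters() -> ModelParameters:
    """Load the packaged reference estimate of the 22 model parameters.

    These are the values estimated from the mouse implant study (residual
    histamine, PMN, and MPhi time courses) and are the generating parameters
    for all synthetic fixtures in this package.
    """
    text = resources.files("phagodyn.data").joinpath("reference_parameters.txt").read_text()
    return ModelParameters.from_mapping(_parse_kv(text))
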