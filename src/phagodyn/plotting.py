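"""Figure-style overlays for trajectories (solid perturbed vs dotted control)."""

from __future__ import annotations

from typing import Sequence

from .model import STATE_NAMES
from .simulate import Trajectory

__all__ = ["plot_trajectories"]


def plot_trajectories(
    perturbed: Trajectory,
    control: Trajectory | None = None,
    variables: Sequence[str] = ("C_rh", "C_pmn", "C_mp"),
    ax=None,
):
    """Plot selected state variables; perturbed solid, control dotted.

    Returns the matplotlib Axes.  Matplotlib is imported lazily so headless
    pipelines that never plot do not pay for it.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for name in variables:
        if name not in STATE_NAMES:
            raise ValueError(f"unknown state variable {name!r}")
        line, = ax.plot(perturbed.times, perturbed.state(name), "-", label=name)
        if control is not None:
            ax.plot(control.times, control.state(name), ":",
                    color=line.get_color(), label=f"{name} (control)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (a.u.)")
    ax.legend(fontsize=8)
    return ax
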