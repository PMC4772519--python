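"""Simulate the inflammation cascade at the reference parameters.

Integrates the eight-state model from an implant at t = 0 (residual
histamine normalized to 1, everything else at zero) and prints the
characteristic time course: histamine stores drain over the first two
hours, the mast-cell source switches on at t1 = 3.5 h with a damped
oscillation, and PMN / MPhi accumulate monotonically.
"""

import numpy as np

from phagodyn import reference_parameters, simulate

p = reference_parameters()
grid = np.arange(0.0, 16.5, 0.5)
traj = simulate(p, None, grid)

print(f"{'t (h)':>6} {'C_rh':>8} {'C_h':>8} {'C_pmn':>8} {'C_mp':>8}")
for t in (0.0, 1.0, 2.0, 3.5, 4.0, 8.0, 12.0, 16.0):
    i = int(np.searchsorted(grid, t))
    print(f"{t:6.1f} {traj.state('C_rh')[i]:8.3f} {traj.state('C_h')[i]:8.3f} "
          f"{traj.state('C_pmn')[i]:8.3f} {traj.state('C_mp')[i]:8.3f}")

print()
print("Residual histamine falls until the source onset (3.5 h), then")
print("recovers with a damped oscillation; recruited phagocyte totals")
print("(C_pmn, C_mp) rise monotonically over the 16-hour window.")
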