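"""Self-recovery study: fit the source/decay constants to noisy model data.

Simulates residual histamine at the reference parameters on the 30-minute
grid, adds white noise (sigma = 0.1), and asks DSLM to re-estimate the
seven source/decay constants from scratch over the default box.  Prints
the recovered values next to the truth.  The onset time t1 is recovered
sharply (the switch-on of the source is a strong feature); the oscillation
parameters (k_w0, k_k2) and the decay rate are only recovered when the
optimizer locks the oscillation, which coordinate-wise search can miss —
see docs/methods.md for the analysis.  This run takes several minutes
(three seeded restarts; the best fit by objective value is reported).
"""

from phagodyn import SOURCE_DECAY_PARAMS, histamine_recovery_experiment

rec = histamine_recovery_experiment(noise_seed=42, fit_seed=(1, 2, 3))

print(f"{'parameter':>10} {'truth':>10} {'recovered':>10}")
for name in SOURCE_DECAY_PARAMS:
    print(f"{name:>10} {getattr(rec.truth, name):10.4f} "
          f"{getattr(rec.recovered, name):10.4f}")
print(f"\nfit score F = {rec.f_best:.4g}  (F at the generating truth: {rec.f_truth:.4g})")
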