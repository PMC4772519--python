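# Methods

## The model

`phagodyn` models the acute phase of the foreign body response to an
implanted biomaterial: the transmigration of phagocytes (polymorphonuclear
neutrophils, PMN, and monocytes/macrophages, MΦ) through the capillary
endothelium toward the implant. Eight coupled ODEs track, in arbitrary
units over hours:

| state    | meaning |
|----------|---------|
| `C_rh`   | residual histamine — granules stored in mast cells |
| `C_h`    | free histamine |
| `C_hr`   | active H1/H2 histamine receptors |
| `C_s`    | P/E selectins on the endothelium |
| `C_pmnp` | capillary permeability for PMN |
| `C_mpp`  | capillary permeability for MΦ |
| `C_pmn`  | total recruited PMN |
| `C_mp`   | total recruited MΦ |

Residual histamine degrades at rate `k_rhch` (degranulation), transferring
mass to free histamine, and is replenished by a *mast-cell source*
`U(t)` — a damped harmonic oscillation around a decaying envelope that
switches on at `t1`:

    U(t) = A(t) + A(t) exp(-β (t - t1)) cos(√(1-β²) ω₀(t) (t - t1)),
    A(t)  = k_e0 exp(-k_k1 (t - t1)),
    ω₀(t) = k_w0 exp(-k_k2 (t - t1)),      U(t) = 0 for t < t1.

Two choices here are deliberate and documented in the code: (i) before the
onset `t1` the source is identically zero, so residual histamine purely
decays over the first hours; (ii) the cosine phase is the literal product
of the instantaneous frequency with the elapsed time (a frequency-chirped
waveform), not the integral of `ω₀(t)` — the two coincide only when
`k_k2 = 0`. Since `|cos| ≤ 1`, `0 ≤ U ≤ 2A(t)`, so the source can never
drive residual histamine negative.

Free histamine activates receptors and selectins through saturating
(hyperbolic / Michaelis-Menten-type) production terms with ceilings
`k_hchrt`, `k_hcst` and half-saturations `k_hchrb`, `k_hcsb`; the receptor ×
selectin product drives capillary permeability through an analogous
hyperbolic term; permeability accumulates directly (coefficient 1) into the
recruited totals, each with first-order clearance. All 22 constants are
non-negative, `0 ≤ β < 1`, and the four half-saturations are strictly
positive; the packaged reference estimate
(`src/phagodyn/data/reference_parameters.txt`) is the default everywhere.

Five indicator functions with values in [0, 1] model interventions:
`I_mc` scales histamine release (mast-cell deficiency), `I_pmnhr`/`I_mphr`
gate the receptor contribution (H1/H2 antagonists), `I_pmns`/`I_mps` gate
the selectin contribution. They are piecewise-constant and right-continuous
at breakpoints. Note that setting `I_mc < 1` deliberately breaks mass
conservation between `C_rh` and `C_h`: the "lost" histamine represents
granules that deficient animals never release.

**Initial conditions.** The measurements this model emulates do not fix
them, so the default is `C_rh(0) = 1` (the first observed value in
normalized units) with every downstream state at zero; this is exposed as a
parameter throughout.

## Numerical integration

LSODA (adaptive, stiff-capable; scipy's `odeint` driver) with `rtol 1e-6`,
`atol 1e-9`. The right-hand side is discontinuous at `t1` and at indicator
breakpoints, so integration restarts at each such time; no internal step
straddles a discontinuity. Halving the tolerances changes sampled states by
well under 1e-4 relative (tested). Sampled states are clip-free; solver
noise can produce values down to about -1e-8, which callers should treat as
zero.

## Scenarios

`Scenario` names four canned interventions (`control`, `mastcell_ko`,
`receptor_ko_after`, `combined_ko`) with a `switch_time` (default 20 h),
`horizon` (default 36 h) and a `ko_level` — the indicator level of the
blocked component. `ko_level` defaults to 0 (complete block) and is logged,
because predictions depend strongly on it: with a complete mast-cell block
and zero initial histamine the model predicts *no* recruitment at all, so
any intermediate outcome (e.g. "about half the control") corresponds to an
intermediate level that must be chosen explicitly.

## Least-squares fitting

The objective is `F(x) = Σ [w_s (ỹ_i − f(t_i, x))]²` over every record of
every dataset, subject to a box `l ≤ x ≤ u`. Default box: [0, 20] for all
rates and amplitudes, [0, 0.99] for β (the oscillation frequency factor
`√(1-β²)` must stay real), [0, horizon] for `t1`. Default per-species
weight: `1 / std(observations of that species)`, so histamine levels and
cell counts enter on comparable scales; multiplying *all* weights by a
common factor provably leaves the optimizer's iterate sequence unchanged.
Multiple datasets are stacked, not averaged (duplicating a dataset exactly
doubles `F`). Model output is sampled on the union of observation times,
never interpolated. Any subset of the 22 parameters may be held fixed.

## The DSLM optimizer

The local solver is a box-constrained damped Gauss-Newton (Levenberg-
Marquardt): solve `(JᵀJ + μI) d = -Jᵀr`, project the trial point onto the
box, accept only if `F` decreases; μ starts at `τ · max diag(JᵀJ)`
(τ = 1e-3), shrinks by the standard gain-ratio rule on accepted steps, and
is multiplied by a doubling factor ν on rejections. Singular normal
equations raise μ instead of aborting. Jacobians are forward differences at
1e-6 relative by default; callers with analytic Jacobians (the benchmarks)
supply them directly. For ODE-based residuals the difference step must sit
above the integrator noise floor, so fitting protocols use 1e-4 relative
(≈ √rtol).

Discrete Selection LM (DSLM) globalizes this: each free parameter's
interval is split into N uniform cells (default 20). A sweep visits the
parameters in index order; for each still-unmarked cell of the current
dimension it launches a full LM run from the incumbent with that coordinate
replaced by the cell midpoint, then marks every cell of that dimension
between the launch cell and the cell of the converged coordinate. Marking
only prunes redundant launches — it never changes where a launch converges,
so the discretization density does not limit accuracy (doubling N never
worsens the result; tested). The best point seen is kept (never worse than
the incumbent), each sweep ends with one full LM polish, marks reset at the
start of each sweep, and the outer loop stops when
`|ΔF| ≤ tol (1 + |F|)` or after `max_outer` (default 100) sweeps. The
launch count per sweep is at most `Σ_j N_j + 1` — linear, not exponential,
in the number of parameters. With a fixed seed (which controls only the
uniform initial draw) the result is bit-reproducible.

Where the published description of the selection step is ambiguous, this
implementation chooses: full-vector LM during selection (a 1-d variant was
evaluated and is strictly weaker — see "Known limitations"); cell midpoints
as launch representatives; fixed index sweep order; per-sweep mark reset.

## Benchmarks

Rastrigin (`10d + Σ(x_i² − 10 cos 2πx_i)` on [-5.12, 5.12]^d, minimum 0 at
the origin) and Michalewicz (`-Σ sin(x_i) sin^{2m}(i x_i²/π)` on [0, π]^d,
m = 10, d! local minima) are exposed both as plain functions and as exact
sum-of-squares decompositions so the LM core applies:
`x² − 10cos(2πx) + 10 = x² + 20 sin²(πx)` gives smooth Rastrigin residuals,
and `r_i = √(1 − s_i)` (each Michalewicz term `s_i ∈ [0, 1]` on the domain)
gives `‖r‖² = d + F(x)`. A floor of 1e-14 inside the square root keeps the
Jacobian finite as `s_i → 1`; reported scores are always the plain function
value at the returned point, never the shifted residual norm. The
assessment harness runs an optimizer over seeded repeats and reports
mean ± std of scores and iteration counts, where a DSLM "iteration" is one
outer sweep. The deterministic oracle (`grid_polish_minimum`) enumerates a
dense tensor grid (d ≤ 2) and polishes the best point; `multistart_lm` is
the brute global baseline.

For the 5-d Michalewicz minimum, the measured per-start probability that a
uniform random start lands every coordinate in its globally optimal valley
is ≈ 9e-5 (the function is separable, so coordinates converge
independently); the multistart protocol therefore uses 80 000 starts,
bounding the miss probability near 1e-3.

## Synthetic data

`mouse_fixture` emulates the sparse measurement design of the underlying
implant experiment: residual histamine at {0, 2, 4, 8, 12, 16} h, PMN and
MΦ at {0, 4, 8, 12, 16} h, four replicates ("mice") per time point. Values
come from the model at the reference parameters with multiplicative
lognormal replicate scatter (σ = 0.12, a moderate biological CV consistent
with the qualitative spread of such assays). What it reproduces is the
*shape* of real data — early histamine decay, post-onset recovery,
monotone phagocyte accumulation, replicate structure — and what it does
not: absolute scales, assay-specific error structure, inter-animal
correlations. Tests passing on these fixtures therefore validate the
pipeline's mechanics and the model's qualitative behavior, not agreement
with any particular animal dataset.

`iwm_smooth` is an outlier-robust per-time-point location estimate:
starting from the arithmetic mean, replicates are reweighted by
`w_k = 1/(ε + |y_k − m|)` (ε = 1e-6 × data scale) until the estimate
stabilizes. It is a surrogate built to the documented purpose of the
original (unavailable) smoothing procedure — down-weighting outlying
replicates; with `tol = ∞` it reduces to the plain mean.

`generate_synthetic_datasets` expands the sparse table into n (default 100)
dense replicate datasets on a 30-minute grid: robust smoothing, then
shape-preserving monotone cubic interpolation (PCHIP — no overshoot below
zero between non-negative knots), then per-grid-point resampling of the
observed relative replicate deviations (a residual bootstrap; relative
deviations are pooled only at time points with meaningfully positive
smoothed level, since relative scatter is undefined at zero).
`simulate_noisy` adds i.i.d. Gaussian noise (default σ = 0.1) to noiseless
model samples and floors at zero, as concentrations are non-negative.

## The recovery experiment and its identifiability limit

`histamine_recovery_experiment` simulates residual histamine at the
reference parameters on the 0:0.5:16 h grid with `C_rh(0) = 1`, adds
N(0, 0.1²) noise, and re-estimates the seven source/decay constants
(`t1, k_e0, k_k1, β, k_w0, k_k2, k_rhch`) with DSLM over the default box,
running three independently seeded restarts and reporting the fit with the
lowest objective — the standard restart protocol for a stochastic global
optimizer (selection is by objective value only). The per-restart budget —
N = 20 cells, 60 LM iterations per launch, FD step 1e-4 relative, up to 8
outer sweeps with a stall criterion of 5e-4 relative improvement per sweep
(hopeless runs stop after two or three sweeps; productive descents, whose
per-sweep gains are orders of magnitude larger, continue) — keeps one
restart to a couple of minutes; the qualitative
outcome is unchanged by a 1e-6 FD step or a 120-iteration cap (verified).

The onset time `t1` is recovered to within about ±0.13 h on every run: the
switch-on of the source is a strong, localized feature. The remaining
constants expose a genuine limitation of coordinate-wise global search on
this landscape. A single DSLM run lands, with measured probability of
roughly 0.9 across seeds, in an attractor family (fit score F ≈ 5.07
versus ≈ 0.006 at the generating truth) in which the frequency-contraction
rate `k_k2` runs large, extinguishing the oscillation within a fraction of
an hour; the initial frequency `k_w0` then has essentially zero gradient,
and dense 1-d line scans through the attractor along either `k_w0` or
`k_k2` change F by less than 1e-3. Escaping requires a *simultaneous* move
of both oscillation parameters into their basins (verified to succeed when
forced by hand), which is exactly the move a one-dimension-at-a-time
selection never makes. The remaining ~10% of runs do reach the global
basin (F below the noise floor, all seven constants recovered, `k_rhch`
within a few percent), so restarts raise the odds but do not guarantee
success: the recovered decay rate `k_rhch` is unreliable under this
protocol, while `t1` is robust. Practical remedies — informative bounds on
the oscillation parameters, or seeding the fit from a preliminary spectral
estimate of the oscillation frequency — would change the protocol and are
therefore left out.

## Known limitations

- DSLM explores one parameter dimension at a time; objectives whose global
  basin requires coordinated moves of two or more parameters (see above)
  can defeat it. The per-sweep cost is linear in dimensions, which is the
  point of the design; the price is exactly this failure mode.
- No identifiability analysis, profile likelihood, or uncertainty
  quantification: fits return point estimates only.
- The model is a well-mixed compartment description — no spatial structure,
  no stochastic (small-copy-number) effects, no additional cell types.
- The benchmark harness implements no genetic-algorithm or simulated-
  annealing optimizers; third-party optimizers can be plugged in as
  callables for comparison tables.
- `run_benchmark` with `grid_polish` is limited to d ≤ 2 (dense tensor
  enumeration).

## Problem sizes used by the shipped protocols

Benchmark assessment: 10 seeded DSLM runs each on 50-d Rastrigin and 10-d
Michalewicz (N = 20); 2-d minima by dense 0.005 grids plus polish; 5-d
Michalewicz by 80 000-start multistart; 10-d Michalewicz by polish from the
known argmin. Recovery: one 33-point dataset, one seeded DSLM fit as
described above. These sizes are the package's standard protocol and are
what `scripts/acceptance.py` and the test suite execute.
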