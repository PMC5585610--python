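# Methods

## Model

The package integrates an 8-dimensional ODE model of a melanoma-bearing
mouse under dendritic-cell (DC) immunotherapy. The state couples the tumor
(`T`, cells) to an immune cascade: injected DCs (`D`) activate CD4 helper
cells (`H`), whose IL-2 (`I`) expands CD8 cytotoxic cells (`C`); CD8 cells
kill tumor cells at a rate saturable in the MHC class-1 receptor density
(`M_I`, upregulated by CD8-derived IFN-γ, `F_γ`) and suppressed by
tumor-derived TGF-β (`F_β`). Tumor growth is Gompertz,
`r_T T log(K_T/T)` with natural logarithm (the standard convention, and
the only one consistent with `r_T` in h⁻¹).

Assumptions inherited from the model class: the tumor is homogeneous and
monoclonal; CD4/CD8 populations are normalized (carrying capacities
`K_H = K_C = 1`), so their absolute scale lives in the interaction
constants; the vaccine transfers antigen but does not prime CD8 cells
directly.

Three printed ambiguities in the source equations are resolved as follows
(all three choices are exercised by tests):

* the DC equation decays as `−μ_D D` (Parameter table: `μ_D` in h⁻¹,
  "death rate of DCs"), not `−μ_D C D`;
* the TGF-β suppression factor uses the dedicated Michaelis constants
  `a_Tβ = 0.69`, `e_Tβ = 1e4 pg` (which otherwise appear nowhere), with
  `e_T = 50` reserved for the MHC-1 saturation;
* the MHC-1 production from IFN-γ is Michaelis–Menten
  `a_Mγ F_γ/(e_Mγ + F_γ)`.

The Gompertz term is defined as 0 at `T = 0` (continuous limit), making
the tumor-free hyperplane invariant. Its closed-form solution and the
tumor-free steady state `(0, a_H/μ_H, a_C/μ_C, 0, 0, 0, a_γC C*/μ_γ,
(a_Mγ F_γ*/(e_Mγ+F_γ*) + g_M)/μ_M)` serve as analytic oracles in the test
suite.

## Impulsive therapy

A schedule lists injection times `t_i` (hours); each bolus of `V` DCs
takes effect at `t_i + τ` (`τ = 232 h`, lymph-node transit) as an
instantaneous jump of the DC coordinate. Two dose conventions exist in
the literature this model descends from: the jump equals `e_f·V` (the
control definition, with `e_f` the delivery efficiency) or the raw `V`
(treating the printed dose as already delivered). The package implements
both behind `TherapyConfig.apply_efficiency` and defaults to `e_f·V`: it
is the convention under which the delivery efficiency is a meaningful
experimental knob, and it reproduces the published with-therapy tumor
masses far more closely than the raw-dose reading (which essentially
eradicates the tumor). Neither convention reproduces the published
maximum/final pair exactly; the residual discrepancy is consistent with
those numbers describing the diameter-converted experimental curve, whose
conversion constant is out of scope here.

Admissibility requires `t_i + τ < t_f`. The two bundled descent-demo
schedules place injections near 880–990 h on a 1000 h horizon, which is
only admissible if their times are read as effective arrival times; those
fixtures therefore carry `τ = 0`. Coincident injections merge into one
summed jump. Integration is exact stop–restart — never smoothed pulses —
so jumps are bit-exact and the logged events conserve total dose exactly.

## Numerics

The system is stiff in two regimes: TGF-β decays fast (`μ_β = 6.93` h⁻¹),
and a fresh bolus pins the CD4 equation at its carrying capacity with a
local eigenvalue of order `−r_H D ≈ −1e4…−1e5` h⁻¹. The default
integrator is BDF with the analytic Jacobian at relative tolerance 1e-8;
absolute tolerance is 1e-8 times the per-coordinate magnitude at each
segment start (floored at 1), which handles the ~12 orders of magnitude
spanned by the state. LSODA was rejected after its stiffness switch was
observed stalling at the explicit stability limit (micro-steps of ~2e-6 h)
in the post-bolus regime. Solver excursions below zero smaller than 1e-9
are clipped; the Gompertz log is evaluated as `log K_T − log T` so that
deeply suppressed tumors (T ~ 1e-300) never overflow. Halving the
tolerances moves the final tumor mass of the laboratory protocol by less
than 0.1%.

## Schedule optimization

The cost is the final tumor burden `T(t_f)`. Moving impulse `i` later by
`dt` perturbs the post-jump state by `[f(x⁻) − f(x⁻ + e_D·dose)]·dt`, so
the terminal sensitivity `v_i(t_f) = dx(t_f)/dt_i` solves the linear
variational system `v' = D_x f(x_s(t)) v` from the impulse time, along the
dense-interpolated reference trajectory. Later impulses are time-fixed
and contribute no first-order term, so the linear flow integrates
straight through them. For coincident injections the initial condition
perturbs only the dose being moved.

The gradient projects `v_i(t_f)` onto the tumor coordinate — the
coordinate the cost measures. A `"dc"` projection mode is kept for
fidelity experiments, but the DC component of the sensitivity is
`μ_D·dose·exp(−μ_D (t_f − s_i)) > 0` identically (the DC row of the
variational system decouples), so it cannot encode a descent direction
for the tumor; the finite-difference oracle (20/20 random instances
within 5%, typically 1e-4) arbitrates for the tumor projection. Likewise
the variational initial condition is applied at the physical jump time
`t_i + τ`; a literal mode starting at `t_i` exists but fails the oracle
whenever `τ > 0`.

Descent steps: `t ← t − h·g`, re-sorted and clamped to `[0, t_f − τ)`.
Three step rules: a raw fixed `h`; a normalized fixed step
(`h = c/max|g_i|`, the steepest time moves `c` hours per iteration); and
the default golden-section line search on `h ∈ [0, cap/max|g_i|]`
(`cap = 250 h` of maximal movement per outer step), shrunk until the
bracket maps to under 1 h and rejected if no trial beats the current
cost — so the cost history is non-increasing by construction. Times may
cross and coalesce; converged schedules are reported with doses merged
over a 0.5 h window. Doses and injection count never change; only times
move.

For long horizons, the interval scheme divides `[0, t_f]` into `m` equal
windows, translates the template schedule into each window, optimizes
window `i` with the carried end state of window `i−1` as initial
condition and the window's right endpoint as its cost horizon, clamps
each window's impulses inside the window, and finally re-simulates the
union schedule over `[0, t_f]`. With `m = 1` this reduces exactly to a
single descent run. Stitched window end states match the full
re-simulation at the boundaries to solver tolerance.

## Periodic-orbit analysis

For a pulse pattern repeated with period `σ`, the stroboscopic map
`F(x₀) = x(σ)` is built from the same impulsive integrator. Fixed points
of `F` are periodic solutions; their residual is normalized per
coordinate by `max(|x₀ₖ|, 1)` because the state spans ~12 orders of
magnitude. The monodromy matrix is the central finite-difference Jacobian
of `F` (relative step 1e-6, integrated at tolerance 1e-10 so the
difference quotient stays above solver noise; coordinates at zero use
one-sided steps to stay in the nonnegative cone). Floquet multipliers are
its eigenvalue moduli: all below `1 − tol` is stable, any above `1 + tol`
unstable, otherwise marginal. A Newton refinement on `F(x) − x = 0` with
that Jacobian is provided. At the tumor-free steady state the Gompertz
derivative is log-singular, so analytic cross-checks (matrix exponential
of `σ·J`, semigroup property) are performed on the 7-dimensional
restriction to the invariant hyperplane `T = 0`. Scope is deliberately
map construction, residual, refinement, and classification — no
continuation or bifurcation tracking. No canonical `σ` is prescribed for
the quasi-periodic long-horizon regimes; the optimization window length
`t_f/m` is the natural candidate.

## Trajectory summaries

`tumor_final`/`tumor_max` read the sample grid (1 h spacing by default).
Oscillation peaks are grid samples exceeding both neighbors with
prominence at least 1% of the peak's own height — a filter against
solver ripple. Relating prominence to the peak's own height rather than
to the running maximum keeps the late small oscillations of a
well-controlled tumor (amplitude ~1e4–1e6 after an early ~1e9 transient)
measurable; a global-maximum rule would discard exactly the feature the
efficiency comparison needs. The stable-oscillation amplitude is the
median of peaks in the trailing quarter of the horizon.

## Experiment sizes and defaults

The bundled scenarios are the published study conditions: initial state
`(6e4, 0, …, 0)`; laboratory protocol 3×1e6 DCs at 168/336/504 h over
1000 h; descent demos with 4×6e5 DCs on 1000 h; long-horizon runs of
20000/10000/5000 h split into 1000 h windows with 4 injections per window
and `e_f = 0.05/0.08/0.10`. Interval optimizations use 10 golden-section
steps per window, the regime in which the line-searched descent has
essentially converged on these problems. The full three-scenario
reproduction takes on the order of ten minutes on one CPU.

## Known limitations

* The descent is local: different step rules can land in different local
  minima of the highly multimodal cost (the published split-coalescence
  pattern versus full coalescence found here — the latter achieves the
  lower cost under this implementation's conventions).
* The model is deterministic and spatially homogeneous; no
  pharmacokinetics of the injection route, no dose-size optimization, no
  parameter estimation from data.
* Synthetic experiments exercise exactly this ODE model; agreement of
  tests says nothing about biological validity beyond the model's own
  calibration.
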