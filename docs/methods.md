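# Methods

This note documents the models, numerical procedures, default parameters and
design choices behind `sirforce`, and states what the diagnostics do and do
not establish.

## Model and assumptions

The full system in (S, I, R) is

    S' = λ − β_γ(t) S I² − (a_raw + μ) S
    I' = β_γ(t) S I² + a_raw S − (g + μ) I
    R' = g I − μ R

with inflow λ, contact transmission β (through the nonlinear incidence
β S I²), environmental transmission a_raw, cure rate g and death rate μ; all
rates are positive, the forcing amplitude γ ≥ 0. Time and population units
are abstract; no calendar mapping is imposed. The total population
η = S + I + R obeys η' = λ − μη exactly, so the nonnegative octant with
η ≤ λ/μ is forward invariant (Gronwall bound). Note: the companion statement
of the invariant region sometimes quotes λ/δ as the ceiling; the derivation
yields λ/μ (δ = g + μ > μ), and tests assert λ/μ.

Since *R* does not feed back, the analysis uses the planar reduction with
α = a_raw + μ and δ = g + μ. The reduction is exact in S'; in I' it replaces
the environmental gain a_raw·S by α·S, a structural redefinition of size μ·S
that the package treats as part of the reduced model's definition (the
reduced system is the model of record for all analysis; the test suite
asserts the discrepancy as an exact identity rather than pretending the two
formulations coincide).

Seasonality enters through β_γ(t) = β(1 + γΨ(ωt)). The default profile
Ψ(x) = 1 + cos x is C^∞, 2π-periodic, has exactly two nondegenerate critical
points per period and gives the forced rate the positive period mean
β(1 + γ). The admissible class nominally requires Ψ > 0 and the default
touches 0 on a measure-zero set; this is immaterial to every computation
here and alternatives plug in via `ForcingSpec`. For γ > 0 the natural phase
space is ℝ² × S¹ with θ' = ω; the package exposes both the non-autonomous
and the autonomous extended form and tests their equivalence.

## Closed-form analysis (unforced)

Equilibrium, Jacobian, trace, thresholds β₁/β₂ and the eigenvalue pair are
evaluated from their closed forms; each is cross-checked numerically
(finite-difference Jacobians, independent root-finding of the trace,
direct eigensolves). The focus/node distinction is always made from the
computed discriminant, not assumed. "Trace = 0" uses an absolute tolerance
of 1e−9 (closed forms are exact; only floating point intervenes).

**Transversality.** d(Re λ)/dβ at each threshold is computed by central
differences of the closed-form eigenvalue real part with step 1e−6·β*,
Richardson extrapolated. The printed closed-form expressions for these
derivatives are evaluated and reported alongside: the upper-threshold
expression matches the finite difference to 1e−6 relative; the
lower-threshold expression does not (it differs in sign and magnitude, and
agrees only if its denominator is squared — evidently a typographical slip),
so the finite difference is authoritative and the printed forms are
comparison-only.

**Criticality.** The first Lyapunov coefficient l1 is computed from the
standard planar normal-form formula (Guckenheimer–Holmes): the field is
shifted to *P*, linearly transformed so the linear part becomes
[[0, −ω₀], [ω₀, 0]] with ω₀ = √det, and the second/third-order partials in
the normal frame are obtained **symbolically** (sympy, exact rational
parameters), so derivative noise is absent. The remaining uncertainty stems
from the floating-point threshold location and is estimated by re-evaluating
at β* ± 1e−9; the sign is certified only when |l1| exceeds ten times this
estimate, otherwise the point is labelled degenerate (Bautin-type
possibility). At the reference triple (λ, α, δ) = (0.9, 0.1, 1.1):
l1(β₁) ≈ −0.0621, l1(β₂) ≈ −0.400. Both are negative: in the normal-form
convention both crossings are supercritical, with the stable cycle living on
the unstable side of each threshold (at β₂ the crossing is traversed in
reverse, which is what the alternative "subcritical" vocabulary describes).
The package reports sign(l1) and leaves the vocabulary to the caller.

## Flow computations

Integration uses `scipy.integrate.solve_ivp` (RK45) with rtol 1e−8,
atol 1e−10 by default. States are clipped to zero only below 1e−14 (with a
logged warning); genuinely negative states raise.

**Limit cycles.** Poincaré section S = S*, downward crossings, chosen
because *P* lies strictly inside the cycle so the section is transverse near
it. Default transient 2000 time units, horizon 5000 (configurable; near
onset the amplitude-scaling driver uses transient 3000 / horizon 9000
because the cycle's attraction weakens like β − β₁). A cycle is reported
when successive crossing states converge below 1e−7 to a fixed point at
least 1e−3 away from *P* in I; the period is the limiting return time; the
nontrivial Floquet multiplier is the central finite difference (step 1e−6)
of the one-dimensional return map — sufficient in the plane, where the
second multiplier is trivially 1 along the flow. Orbit extrema are refined
by local quadratic interpolation of a 2000-point sampling.

**Bifurcation diagram.** Per β the post-transient (3000 time units) extrema
of I over a 500-unit window are recorded; cycle presence is a spread above
1e−6. This direct method is accurate to the grid resolution used in the
tests (band endpoints within one grid step of β₁, β₂).

**Invariant-region sweeps.** Ensembles integrate as one vectorized
solve_ivp call; the acceptance test uses 1000 random starts in [0, 5]³ over
200 time units, so initial totals lie below the asymptote λ/μ = 18 and the
bound η ≤ λ/μ + 1e−6 must hold along the whole trajectory.

## Chaos diagnostics (forced)

Long-horizon diagnostics use fixed-step RK4 kernels (default dt 0.005,
JIT-compiled with numba) for the default forcing profile; the kernels are
cross-checked against solve_ivp in the tests.

**Largest Lyapunov exponent.** Two-trajectory Benettin method: initial
separation 1e−8 in a seeded random direction (seed 42 default; the only
stochastic input), renormalization every 1.0 time unit, transient 2000,
averaging horizon 20000 time units. Both copies share the forcing phase, so
the neutral phase direction is excluded by construction and the estimate
refers to the (S, I) dynamics; an `extended` variant perturbing (S, I, θ)
is provided and exhibits the exactly-neutral phase exponent. Convergence
requires the last-half running-estimate spread below 0.1·max(|lle|, 0.01).
The noise floor measured on the unforced torus is ~2e−4, well below the
chaos threshold 0.005 per time unit.

**Stroboscopic sections and classification.** Sections sample (S, I) at
t_k = θ₀/ω + k·2π/ω, discarding 500 transient periods and keeping 500.
Geometry evidence: diameter below 1e−5 → point attractor; a cyclic shift
k ≤ 32 mapping the sequence onto itself within 1e−4·scale → mode-locked
periodic orbit; nearest-neighbor gap ratio (max/median < 5) → closed
invariant curve. Labels combine geometry with the exponent: curve + |lle| ≤
0.005 → quasiperiodic torus; lle > 0.005 with convergence → chaotic;
ambiguous evidence is labelled with an explicit low-confidence flag.

**Torus-breakdown sweep and chaotic fraction.** The sweep classifies the
attractor per ω at fixed γ; the chaotic fraction counts grid points with a
converged exponent above threshold over a γ-grid at fixed ω (default ω = 5,
grid on [0, 0.005] — the theoretical amplitude bound is never quantified, so
this scan ceiling is a package choice, flagged as such).

### Negative result of the chaos search

Under the default smooth forcing the package finds **no observable chaos**
in the small-amplitude, high-frequency regime: across γ ∈ [5e−4, 5e−3] ×
ω ∈ [4, 6] at β = (β₁+β₂)/2 the estimated exponents stay within ±5e−4 of
zero (quasiperiodic torus), and wider probes (γ up to 5, ω from 0.2 to 30,
β near both band edges, and a sharp pulse-like profile) produce only
quasiperiodic, mode-locked or strongly contracted attractors. High-frequency
smooth forcing of this size averages out (the exponents become independent
of ω for ω ≫ 1), and near-resonant strong forcing mode-locks. The underlying
theory guarantees strange attractors only for a positive-measure set of
amplitudes in an asymptotic regime; that set is evidently too thin (or the
exponents too small) to observe at these parameter scales with this profile.
The sweep and fraction operations therefore report the torus labels they
measure, and `chaos_fraction` at the default conditions computes 0.0. This
is a property of the measurements, honestly reported, not a failure mode of
the estimators (which resolve both signs of the exponent elsewhere).

## Synthetic-data stance

The package generates all of its own inputs (parameter records and forcing
profiles); there is no external data. What the tests establish is therefore
internal consistency of the dynamical analysis — closed forms against
independent numerics, formulations against each other, scaling laws against
simulations — not agreement with epidemiological observations. Real
epidemic data would add demographic stochasticity, age structure,
reporting noise and non-sinusoidal seasonality, none of which are modelled.

## Known limitations

* Criticality is computed for the planar system only; no center-manifold or
  codimension-2 (Bautin/Bogdanov–Takens) machinery.
* Cycle detection is simulation-based (no continuation or validated
  enclosures); extremely weakly attracting cycles (within ~5e−3 of a
  threshold) may exceed the default horizons and report `undecided`.
* Compiled chaos kernels support the default forcing profile; custom
  profiles fall back to the (slow) adaptive path for trajectories and are
  not supported by the Benettin/stroboscopic drivers.
* The chaotic-fraction scan is a finite-grid analogue of a measure-theoretic
  statement; a zero measured fraction bounds only what the grid resolves.
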