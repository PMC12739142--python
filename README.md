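# sirforce

Qualitative-dynamics toolkit for a seasonally forced SIR epidemic model with
nonlinear incidence and environmental transmission.

## The model

The population is split into susceptibles *S*, infectives *I* and recovered
*R*. Two features distinguish the model from the classic SIR setup:

* **Nonlinear incidence** β S I²: new infections are amplified by local
  case clustering rather than scaling linearly in *I*.
* **Environmental transmission** α: susceptibles are also infected by direct
  contact with the natural viral source, independently of *I*. As a
  consequence there is **no disease-free equilibrium** — the disease is
  structurally endemic.

Because the (S, I) equations decouple from *R*, the analysis works with the
reduced planar system (loss rates absorbed: α ← α + μ, δ = g + μ):

    S' = λ − β_γ(t) S I² − α S
    I' = β_γ(t) S I² + α S − δ I

with seasonally forced transmission rate

    β_γ(t) = β (1 + γ Ψ(ω t)),    Ψ(x) = 1 + cos x  (default profile).

**Unforced regime (γ = 0).** The unique equilibrium is

    P = (S*, I*) = ( δ²λ / (αδ² + βλ²),  λ/δ ),

and the trace of the Jacobian at *P* vanishes at two transmission-rate
thresholds (existing iff 8α < δ)

    β₁,₂ = (−2α + δ ∓ √(δ² − 8αδ)) δ² / (2λ²).

*P* is a stable focus for β < β₁ or β > β₂ and an unstable focus in between;
at each threshold the system undergoes a Hopf bifurcation, and inside the
window an attracting limit cycle (recurrent epidemics) exists. The package
verifies transversality by eigenvalue continuation and decides criticality
from the first Lyapunov coefficient of the planar normal form.

**Forced regime (γ > 0).** The cycle crossed with the forcing phase is an
attracting invariant torus; the package provides stroboscopic Poincaré
sections, Benettin estimates of the largest Lyapunov exponent, attractor
classification (equilibrium / periodic / quasiperiodic torus / chaotic),
torus-breakdown sweeps in ω and a chaotic-fraction scan over the forcing
amplitude.

## Worked example

```bash
python examples/02_limit_cycle.py
```

prints

```
beta = (beta1+beta2)/2 = 0.672222: cycle
  period          : 8.1631 time units
  I on the cycle  : [0.4000, 1.7233]
  S on the cycle  : [0.6220, 2.6741]
  Floquet modulus : 0.2835  (< 1 means attracting)
beta below the band (0.1432): equilibrium
beta above the band (1.2013): equilibrium
```

At the midpoint of the Hopf window the attractor is a limit cycle: infective
counts oscillate between 0.40 and 1.72 around the endemic level I* = λ/δ =
0.818 with period ≈ 8.16 time units, and the nontrivial Floquet multiplier
0.28 < 1 certifies the cycle attracts. Just outside the window the same
search converges to the (stable) endemic equilibrium instead. The other
`examples/` scripts cover the equilibrium/threshold analysis, Hopf
criticality and amplitude scaling, the bifurcation diagram, the invariant
torus, and the torus-breakdown sweep.

A thin CLI mirrors the library:

```bash
sirforce presets
sirforce equilibria --preset fig4ii
sirforce cycle --beta 0.672222
sirforce sweep --gamma 0.001 --omega 0.1,0.5,1,1.5,5
```

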