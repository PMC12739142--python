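"""Endemic equilibrium and the Hopf window of the transmission rate.

The unforced model has a single equilibrium, and it is endemic: because
susceptibles are also infected by direct contact with the environmental
viral source, the disease cannot die out.  Stability of that equilibrium is
controlled entirely by the contact transmission rate beta: the equilibrium
is a stable focus outside a window (beta1, beta2) and unstable inside it.
"""

import numpy as np

from sirforce import (
    ReducedParams,
    classify_equilibrium,
    endemic_equilibrium,
    hopf_thresholds,
    rhs_reduced,
)

params = ReducedParams(lam=0.9, beta=0.672222, alpha=0.1, delta=1.1)

P = endemic_equilibrium(params)
print(f"endemic equilibrium: S* = {P.S_star:.6f}, I* = {P.I_star:.6f}")
print(f"field residual there: {np.abs(rhs_reduced(0.0, P.point, params)).max():.2e}")

th = hopf_thresholds(params)
print(f"Hopf thresholds: beta1 = {th.beta1:.7f}, beta2 = {th.beta2:.7f}")

for beta in (th.beta1 - 0.1, params.beta, th.beta2 + 0.1):
    label = classify_equilibrium(params.with_beta(beta))
    print(f"  beta = {beta:.4f}: {label}")

print("\nI* = lam/delta stays positive for every beta: the infection is")
print("endemic; beta only decides whether prevalence settles (stable focus)")
print("or oscillates (unstable focus surrounded by a limit cycle).")
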