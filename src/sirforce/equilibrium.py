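"""Equilibrium and linear stability analysis of the unforced planar system.

The unforced reduced system has no disease-free equilibrium (environmental
transmission keeps I' = lam > 0 on the I = 0 axis) and a unique endemic
equilibrium

    P = (S*, I*) = (delta**2 * lam / (alpha * delta**2 + beta * lam**2),
                    lam / delta).

The trace of the Jacobian at P changes sign at two transmission-rate
thresholds beta_1 < beta_2 (which exist iff 8*alpha < delta), producing the
stable-focus / unstable-focus / stable-focus pattern in beta and a Hopf
bifurcation at each threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import rhs_reduced
from .params import ParameterError, ReducedParams

#: absolute tolerance below which the trace is treated as exactly zero
TRACE_TOL = 1e-9


@dataclass(frozen=True)
class EndemicEquilibrium:
    """The unique (endemic) equilibrium of the unforced planar system."""

    S_star: float
    I_star: float

    @property
    def point(self) -> np.ndarray:
        return np.array([self.S_star, self.I_star])


@dataclass(frozen=True)
class JacobianSummary:
    """Jacobian of the planar vector field at a point, with spectral data."""

    entries: np.ndarray
    trace: float
    determinant: float
    discriminant: float          # trace**2 - 4*det
    eigenvalues: np.ndarray      # complex pair


@dataclass(frozen=True)
class HopfThresholds:
    """Transmission-rate values where the trace at P vanishes."""

    exists: bool
    beta1: Optional[float] = None
    beta2: Optional[float] = None


def endemic_equilibrium(params: ReducedParams) -> EndemicEquilibrium:
    """Closed-form endemic equilibrium of the unforced system."""
    lam, beta, alpha, delta = params.lam, params.beta, params.alpha, params.delta
    S = delta ** 2 * lam / (alpha * delta ** 2 + beta * lam ** 2)
    return EndemicEquilibrium(S_star=S, I_star=lam / delta)


def cubic_equilibrium_roots(params: ReducedParams) -> tuple[np.ndarray, np.ndarray]:
    """Roots of the equilibrium cubic -beta*delta*I^3 + beta*lam*I^2
    - alpha*delta*I + alpha*lam = 0, with an admissibility mask.

    Exactly one root is real and positive (I = lam/delta); the other two form
    a purely imaginary pair +/- sqrt(-alpha*beta)/beta.  All three roots are
    returned; the mask marks the admissible (real, positive) one.
    """
    lam, beta, alpha, delta = params.lam, params.beta, params.alpha, params.delta
    coeffs = [-beta * delta, beta * lam, -alpha * delta, alpha * lam]
    roots = np.roots(coeffs)
    admissible = (np.abs(roots.imag) < 1e-10) & (roots.real > 0)
    return roots, admissible


def jacobian_at(point, params: ReducedParams) -> JacobianSummary:
    """Jacobian of the unforced planar field at an arbitrary point."""
    S, I = np.asarray(point, dtype=float)
    beta, alpha, delta = params.beta, params.alpha, params.delta
    entries = np.array([[-beta * I ** 2 - alpha, -2.0 * beta * S * I],
                        [beta * I ** 2 + alpha, 2.0 * beta * S * I - delta]])
    tr = float(np.trace(entries))
    det = float(np.linalg.det(entries))
    disc = tr * tr - 4.0 * det
    if disc < 0:
        root = 1j * math.sqrt(-disc)
    else:
        root = math.sqrt(disc)
    eigs = np.array([(tr - root) / 2.0, (tr + root) / 2.0])
    return JacobianSummary(entries=entries, trace=tr, determinant=det,
                           discriminant=disc, eigenvalues=eigs)


def trace_at_equilibrium(params: ReducedParams, beta: Optional[float] = None) -> float:
    """Trace of the Jacobian at P as a closed-form function of beta."""
    lam, alpha, delta = params.lam, params.alpha, params.delta
    b = params.beta if beta is None else beta
    denom = alpha * delta ** 2 + b * lam ** 2
    return (-alpha * delta ** 2 - b * lam ** 2) / delta ** 2 \
        + delta * (-alpha * delta ** 2 + b * lam ** 2) / denom


def hopf_thresholds(params: ReducedParams) -> HopfThresholds:
    """Closed-form trace-zero thresholds beta_1 <= beta_2.

    They exist (as a positive real pair) iff ``8*alpha < delta`` and coincide
    when ``8*alpha == delta``.  The ``beta`` field of ``params`` is ignored.
    """
    lam, alpha, delta = params.lam, params.alpha, params.delta
    disc = delta ** 2 - 8.0 * alpha * delta
    if disc < 0:
        return HopfThresholds(exists=False)
    root = math.sqrt(disc)
    beta1 = (-2.0 * alpha + delta - root) * delta ** 2 / (2.0 * lam ** 2)
    beta2 = (-2.0 * alpha + delta + root) * delta ** 2 / (2.0 * lam ** 2)
    return HopfThresholds(exists=True, beta1=beta1, beta2=beta2)


def classify_equilibrium(params: ReducedParams,
                         trace_tol: float = TRACE_TOL) -> str:
    """Stability label of P from the computed eigenvalues.

    Returns one of ``stable_focus``, ``unstable_focus``, ``stable_node``,
    ``unstable_node`` or ``nonhyperbolic`` (trace within ``trace_tol`` of
    zero, signalling a bifurcation point).  The focus/node distinction is made
    from the computed discriminant rather than assumed.
    """
    P = endemic_equilibrium(params)
    jac = jacobian_at(P.point, params)
    if abs(jac.trace) < trace_tol:
        return "nonhyperbolic"
    focus = jac.discriminant < 0
    if jac.trace < 0:
        return "stable_focus" if focus else "stable_node"
    return "unstable_focus" if focus else "unstable_node"


def equilibrium_report(params: ReducedParams) -> dict:
    """Bundle point, Jacobian summary and stability label for reporting."""
    P = endemic_equilibrium(params)
    jac = jacobian_at(P.point, params)
    residual = rhs_reduced(0.0, P.point, params.unforced())
    return {
        "S_star": P.S_star,
        "I_star": P.I_star,
        "residual": residual,
        "trace": jac.trace,
        "determinant": jac.determinant,
        "discriminant": jac.discriminant,
        "eigenvalues": jac.eigenvalues,
        "label": classify_equilibrium(params),
    }


def _require_thresholds(params: ReducedParams) -> tuple[float, float]:
    th = hopf_thresholds(params)
    if not th.exists:
        raise ParameterError(
            "Hopf thresholds do not exist: require 8*alpha < delta "
            f"(alpha={params.alpha}, delta={params.delta})")
    return th.beta1, th.beta2
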