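"""Hopf bifurcation machinery: eigenvalue continuation, transversality and
criticality via the first Lyapunov coefficient.

At each trace-zero threshold the Jacobian at the endemic equilibrium has a
purely imaginary conjugate pair ``+/- i*w0``.  Transversality (the real part
of the pair crossing zero with nonzero speed in beta) is established by a
Richardson-extrapolated central finite difference of ``Re lambda(beta)``; the
printed closed-form expressions for these derivatives are evaluated alongside
for comparison but the finite difference is authoritative (the two printed
forms are structurally inconsistent with each other — one denominator is
squared, the other is not — and only one matches the numerical derivative).

Criticality is decided by the sign of the first Lyapunov coefficient ``l1``
of the planar Hopf normal form, computed from exact symbolic third-order
partial derivatives of the vector field in the normal frame
(Guckenheimer–Holmes planar formula).  ``l1 < 0`` means a stable limit cycle
bifurcates (supercritical in the normal-form convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sympy as sp

from .equilibrium import (
    _require_thresholds,
    endemic_equilibrium,
    jacobian_at,
    trace_at_equilibrium,
)
from .params import ReducedParams


@dataclass(frozen=True)
class TransversalityResult:
    branch: str                 # "lower" (beta_1) or "upper" (beta_2)
    beta_star: float
    fd: float                   # Richardson-extrapolated central difference
    closed_form: float          # printed expression, reported for comparison


@dataclass(frozen=True)
class LyapunovCoefficient:
    l1: float
    w0: float                   # imaginary part of the pair at the threshold
    error_estimate: float
    criticality: str            # supercritical | subcritical | degenerate


@dataclass(frozen=True)
class HopfReport:
    beta_star: float
    branch: str
    transversality_fd: float
    transversality_cf: float
    l1: float
    criticality: str


def eigenvalues_closed_form(params: ReducedParams) -> tuple[np.ndarray, bool]:
    """Eigenvalue pair at P from the closed-form trace and determinant.

    Returns ``(pair, is_complex)``.  When the discriminant is negative the
    pair is complex conjugate; otherwise the direct real eigensolve result is
    returned with ``is_complex=False`` (fallback path).
    """
    P = endemic_equilibrium(params)
    jac = jacobian_at(P.point, params)
    tr, disc = jac.trace, jac.discriminant
    if disc < 0:
        root = 1j * math.sqrt(-disc)
        pair = np.array([(tr - root) / 2.0, (tr + root) / 2.0])
        return pair, True
    return jac.eigenvalues, False


def _re_lambda(params: ReducedParams, beta: float) -> float:
    """Real part of the leading eigenvalue pair of the Jacobian at P(beta)."""
    p = params.with_beta(beta)
    pair, is_complex = eigenvalues_closed_form(p)
    if is_complex:
        return float(pair[0].real)
    return float(np.max(pair.real))


def _closed_form_transversality(params: ReducedParams, branch: str) -> float:
    """The printed derivative expressions at beta_1 / beta_2 (as printed)."""
    lam, alpha, delta = params.lam, params.alpha, params.delta
    root = math.sqrt(delta ** 2 - 8.0 * alpha * delta)
    if branch == "lower":
        return lam ** 2 * (root + 8.0 * alpha - delta) / (delta * (-delta + root))
    return lam ** 2 * (-root + 8.0 * alpha - delta) / (delta * (delta + root) ** 2)


def transversality(params: ReducedParams, branch: str,
                   rel_step: float = 1e-6) -> TransversalityResult:
    """d(Re lambda)/d(beta) at a Hopf threshold, finite-difference based.

    Central differences with step ``rel_step * beta_star`` are Richardson
    extrapolated (steps h and h/2).  Raises if the thresholds do not exist.
    """
    if branch not in ("lower", "upper"):
        raise ValueError(f"branch must be 'lower' or 'upper', got {branch!r}")
    beta1, beta2 = _require_thresholds(params)
    beta_star = beta1 if branch == "lower" else beta2

    def central(h: float) -> float:
        return (_re_lambda(params, beta_star + h)
                - _re_lambda(params, beta_star - h)) / (2.0 * h)

    h = rel_step * beta_star
    d_h, d_h2 = central(h), central(h / 2.0)
    fd = (4.0 * d_h2 - d_h) / 3.0
    return TransversalityResult(branch=branch, beta_star=beta_star, fd=fd,
                                closed_form=_closed_form_transversality(params, branch))


def _normal_frame_exprs(params: ReducedParams, beta_star: float,
                        time_scale: float = 1.0):
    """Planar field at beta_star in the Hopf normal frame, symbolically.

    Returns (f, g, u, v, w0): the transformed field components as sympy
    expressions in the normal-frame coordinates (u, v), with linear part
    ``u' = -w0 v, v' = w0 u``.
    """
    lam = sp.Rational(str(params.lam))
    alpha = sp.Rational(str(params.alpha))
    delta = sp.Rational(str(params.delta))
    beta = sp.Rational(str(beta_star))
    S, I = sp.symbols("S I")
    fS = lam - beta * S * I ** 2 - alpha * S
    fI = beta * S * I ** 2 + alpha * S - delta * I
    scale = sp.Rational(str(time_scale))
    fS, fI = scale * fS, scale * fI

    Sst = delta ** 2 * lam / (alpha * delta ** 2 + beta * lam ** 2)
    Ist = lam / delta
    A = sp.Matrix([[sp.diff(fS, S), sp.diff(fS, I)],
                   [sp.diff(fI, S), sp.diff(fI, I)]]).subs({S: Sst, I: Ist})
    det = sp.simplify(A.det())
    if det <= 0:
        raise ValueError("determinant at P must be positive at a Hopf point")
    w0 = sp.sqrt(det)
    a11, a12 = A[0, 0], A[0, 1]
    # eigenvector for +i*w0 is (a12, i*w0 - a11); real frame columns (vi, vr)
    T = sp.Matrix([[0, a12], [w0, -a11]])
    u, v = sp.symbols("u v")
    X = sp.Matrix([Sst, Ist]) + T * sp.Matrix([u, v])
    F = T.inv() * sp.Matrix([fS.subs({S: X[0], I: X[1]}),
                             fI.subs({S: X[0], I: X[1]})])
    return sp.expand(F[0]), sp.expand(F[1]), u, v, w0


def _l1_value(params: ReducedParams, beta_star: float,
              time_scale: float = 1.0) -> tuple[float, float]:
    f, g, u, v, w0 = _normal_frame_exprs(params, beta_star, time_scale)

    def d(expr, *syms):
        return sp.diff(expr, *syms).subs({u: 0, v: 0})

    cubic = (d(f, u, u, u) + d(f, u, v, v) + d(g, u, u, v) + d(g, v, v, v)) / 16
    mixed = (d(f, u, v) * (d(f, u, u) + d(f, v, v))
             - d(g, u, v) * (d(g, u, u) + d(g, v, v))
             - d(f, u, u) * d(g, u, u) + d(f, v, v) * d(g, v, v)) / (16 * w0)
    return float(sp.N(cubic + mixed, 30)), float(sp.N(w0, 30))


def first_lyapunov_coefficient(params: ReducedParams, beta_star: float,
                               time_scale: float = 1.0,
                               trace_tol: float = 1e-6) -> LyapunovCoefficient:
    """First Lyapunov coefficient of the planar normal form at beta_star.

    Requires the trace at P to vanish at ``beta_star`` (within ``trace_tol``).
    Derivatives are exact (symbolic); the remaining uncertainty comes from the
    floating-point location of ``beta_star`` and is estimated by re-evaluating
    at ``beta_star +/- 1e-9``.  The sign is certified only when ``|l1|``
    exceeds ten times that estimate, otherwise the point is labelled
    ``degenerate`` (a Bautin-type possibility).
    """
    tr = trace_at_equilibrium(params, beta_star)
    if abs(tr) > trace_tol:
        raise ValueError(
            f"trace at P is {tr:.3e} at beta={beta_star}; not a Hopf point")
    l1, w0 = _l1_value(params, beta_star, time_scale)
    h = 1e-9 * max(1.0, abs(beta_star))
    l1_hi, _ = _l1_value(params, beta_star + h, time_scale)
    l1_lo, _ = _l1_value(params, beta_star - h, time_scale)
    err = max(abs(l1_hi - l1), abs(l1_lo - l1), 1e-12 * abs(l1))
    if abs(l1) <= 10.0 * err:
        crit = "degenerate"
    else:
        crit = "supercritical" if l1 < 0 else "subcritical"
    return LyapunovCoefficient(l1=l1, w0=w0, error_estimate=err, criticality=crit)


def hopf_report(params: ReducedParams, branch: str) -> HopfReport:
    tv = transversality(params, branch)
    lc = first_lyapunov_coefficient(params, tv.beta_star)
    return HopfReport(beta_star=tv.beta_star, branch=branch,
                      transversality_fd=tv.fd, transversality_cf=tv.closed_form,
                      l1=lc.l1, criticality=lc.criticality)


def hopf_scan(params: ReducedParams, beta_grid: Sequence[float],
              bisect_tol: float = 1e-10) -> list[HopfReport]:
    """Detect all trace-zero crossings of beta on a grid and refine each.

    Sign changes of the closed-form trace along the (sorted, positive) grid
    are refined by bisection to ``bisect_tol`` in beta; a full
    :class:`HopfReport` is emitted per crossing.
    """
    grid = np.asarray(beta_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("beta grid is empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("beta grid must be positive and strictly increasing")
    traces = np.array([trace_at_equilibrium(params, b) for b in grid])
    reports: list[HopfReport] = []
    for i in np.nonzero(traces[:-1] * traces[1:] < 0)[0]:
        lo, hi = grid[i], grid[i + 1]
        f_lo = traces[i]
        while hi - lo > bisect_tol:
            mid = 0.5 * (lo + hi)
            f_mid = trace_at_equilibrium(params, mid)
            if f_lo * f_mid <= 0:
                hi = mid
            else:
                lo, f_lo = mid, f_mid
        beta_star = 0.5 * (lo + hi)
        # trace goes - -> + at the lower threshold, + -> - at the upper one
        branch = "lower" if traces[i] < 0 else "upper"
        tv = transversality(params, branch)
        lc = first_lyapunov_coefficient(params, beta_star)
        reports.append(HopfReport(beta_star=beta_star, branch=branch,
                                  transversality_fd=tv.fd,
                                  transversality_cf=tv.closed_form,
                                  l1=lc.l1, criticality=lc.criticality))
    return reports
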