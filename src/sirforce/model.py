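"""Vector fields of the forced SIR model with nonlinear incidence.

Three equivalent formulations are provided:

* the full three-dimensional system in (S, I, R),
* the reduced planar system in (S, I) obtained by absorbing the death rate
  into the loss rates (the R equation decouples),
* the autonomous extension on R^2 x S^1 in (S, I, theta) where the forcing
  phase theta advances at constant speed omega.

Incidence is nonlinear, ``beta_gamma(t) * S * I**2``, and susceptibles are
additionally infected at rate proportional to direct contact with the
environmental viral source, so no disease-free equilibrium exists.
"""

from __future__ import annotations

import math
from typing import Sequence, Union

import numpy as np

from .forcing import DEFAULT_FORCING, ForcingSpec
from .params import FullParams, ParameterError, ReducedParams

ArrayLike = Union[Sequence[float], np.ndarray]

#: tolerance below which a state component is treated as an integration
#: round-off artifact rather than a genuinely negative population
_NEG_TOL = 1e-8


def _check_state(x: np.ndarray) -> None:
    if np.any(np.asarray(x) < -_NEG_TOL):
        raise ValueError(f"state has negative components: {np.asarray(x)}")


def transmission_rate(t: ArrayLike, params: ReducedParams,
                      forcing: ForcingSpec = DEFAULT_FORCING):
    """Seasonally modulated transmission rate beta * (1 + gamma * psi(omega*t)).

    Reduces to the constant ``beta`` when ``gamma == 0`` and is periodic in t
    with period ``forcing.period_T / omega`` otherwise.
    """
    t = np.asarray(t, dtype=float)
    if params.gamma == 0.0:
        return params.beta * np.ones_like(t) if t.ndim else params.beta
    value = params.beta * (1.0 + params.gamma * forcing.psi(params.omega * t))
    return value if t.ndim else float(value)


def rhs_full(t: float, x: ArrayLike, params: FullParams,
             forcing: ForcingSpec = DEFAULT_FORCING) -> np.ndarray:
    """Time derivative of the full (S, I, R) system.

    The componentwise sum equals ``lam - mu * (S + I + R)``, which is the
    channel through which the Gronwall bound on the total population operates.
    """
    S, I, R = np.asarray(x, dtype=float)
    _check_state([S, I, R])
    bg = params.beta * (1.0 + params.gamma * forcing.psi(params.omega * t)) \
        if params.gamma > 0 else params.beta
    incidence = bg * S * I * I
    env = (params.a_raw + params.mu) * S
    dS = params.lam - incidence - env
    dI = incidence + params.a_raw * S - (params.g + params.mu) * I
    dR = params.g * I - params.mu * R
    return np.array([dS, dI, dR])


def rhs_reduced(t: float, x: ArrayLike, params: ReducedParams,
                forcing: ForcingSpec = DEFAULT_FORCING) -> np.ndarray:
    """Time derivative of the reduced planar (S, I) system."""
    S, I = np.asarray(x, dtype=float)
    _check_state([S, I])
    bg = params.beta * (1.0 + params.gamma * forcing.psi(params.omega * t)) \
        if params.gamma > 0 else params.beta
    incidence = bg * S * I * I
    dS = params.lam - incidence - params.alpha * S
    dI = incidence + params.alpha * S - params.delta * I
    return np.array([dS, dI])


def rhs_extended(x: ArrayLike, params: ReducedParams,
                 forcing: ForcingSpec = DEFAULT_FORCING) -> np.ndarray:
    """Autonomous extension on R^2 x S^1: forcing phase as a state variable.

    ``(S, I)`` evolve as in the reduced system with the transmission rate
    evaluated through ``psi(theta)``; the phase advances as ``theta' = omega``
    (taken mod 2*pi by the integrators).
    """
    if params.omega <= 0:
        raise ParameterError(
            f"omega must be positive for the extended system, got {params.omega}")
    S, I, theta = np.asarray(x, dtype=float)
    _check_state([S, I])
    bg = params.beta * (1.0 + params.gamma * forcing.psi(theta)) \
        if params.gamma > 0 else params.beta
    incidence = bg * S * I * I
    dS = params.lam - incidence - params.alpha * S
    dI = incidence + params.alpha * S - params.delta * I
    return np.array([dS, dI, params.omega])


def reduce_full_state(x3: ArrayLike) -> np.ndarray:
    """Project a full (S, I, R) state onto the reduced (S, I) plane."""
    return np.asarray(x3, dtype=float)[:2]


def wrap_phase(theta: float) -> float:
    """Wrap a phase angle into [0, 2*pi)."""
    return theta % (2.0 * math.pi)
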