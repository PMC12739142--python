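"""Compiled fixed-step integrators for long-horizon chaos diagnostics.

Benettin exponent estimation and stroboscopic sampling need millions of
right-hand-side evaluations; adaptive solver calls per renormalization
interval would dominate runtime.  These kernels implement classic RK4 with a
fixed step for the reduced forced system under the default forcing profile
``psi(x) = 1 + cos(x)`` and are JIT-compiled with numba.  They are
cross-checked against the adaptive scipy path in the test suite; custom
forcing profiles take the (slower) scipy path in :mod:`sirforce.chaos`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=False)
def _rhs(t, S, I, lam, beta, alpha, delta, gamma, omega):
    bg = beta * (1.0 + gamma * (1.0 + math.cos(omega * t)))
    inc = bg * S * I * I
    return lam - inc - alpha * S, inc + alpha * S - delta * I


@njit(cache=False)
def _rk4_step(t, S, I, dt, lam, beta, alpha, delta, gamma, omega):
    k1S, k1I = _rhs(t, S, I, lam, beta, alpha, delta, gamma, omega)
    k2S, k2I = _rhs(t + 0.5 * dt, S + 0.5 * dt * k1S, I + 0.5 * dt * k1I,
                    lam, beta, alpha, delta, gamma, omega)
    k3S, k3I = _rhs(t + 0.5 * dt, S + 0.5 * dt * k2S, I + 0.5 * dt * k2I,
                    lam, beta, alpha, delta, gamma, omega)
    k4S, k4I = _rhs(t + dt, S + dt * k3S, I + dt * k3I,
                    lam, beta, alpha, delta, gamma, omega)
    return (S + dt / 6.0 * (k1S + 2.0 * k2S + 2.0 * k3S + k4S),
            I + dt / 6.0 * (k1I + 2.0 * k2I + 2.0 * k3I + k4I))


@njit(cache=False)
def run_segment(t0, S, I, t_len, dt, lam, beta, alpha, delta, gamma, omega):
    """Advance one trajectory by t_len using n = round(t_len/dt) RK4 steps."""
    n = int(round(t_len / dt))
    h = t_len / n
    t = t0
    for _ in range(n):
        S, I = _rk4_step(t, S, I, h, lam, beta, alpha, delta, gamma, omega)
        t += h
    return S, I


@njit(cache=False)
def benettin_history(S0, I0, u0, u1, d0, t_transient, t_total, renorm_dt, dt,
                     lam, beta, alpha, delta, gamma, omega):
    """Two-trajectory Benettin estimate of the top planar exponent.

    Both trajectories share the same (non-autonomous) time, so the neutral
    forcing-phase direction is excluded by construction and the estimate
    refers to the (S, I) dynamics alone.  Returns the running-estimate
    history, one entry per renormalization interval.
    """
    t = 0.0
    S, I = run_segment(t, S0, I0, t_transient, dt, lam, beta, alpha, delta,
                       gamma, omega)
    t = t_transient
    Sp = S + d0 * u0
    Ip = I + d0 * u1
    n_ren = int(round(t_total / renorm_dt))
    hist = np.empty(n_ren)
    acc = 0.0
    for k in range(n_ren):
        n = int(round(renorm_dt / dt))
        h = renorm_dt / n
        for _ in range(n):
            S, I = _rk4_step(t, S, I, h, lam, beta, alpha, delta, gamma, omega)
            Sp, Ip = _rk4_step(t, Sp, Ip, h, lam, beta, alpha, delta, gamma,
                               omega)
            t += h
        d = math.sqrt((Sp - S) ** 2 + (Ip - I) ** 2)
        acc += math.log(d / d0)
        hist[k] = acc / ((k + 1) * renorm_dt)
        scale = d0 / d
        Sp = S + (Sp - S) * scale
        Ip = I + (Ip - I) * scale
    return hist


@njit(cache=False)
def benettin_extended_history(S0, I0, th0, u0, u1, u2, d0, t_transient,
                              t_total, renorm_dt, dt,
                              lam, beta, alpha, delta, gamma, omega):
    """Benettin estimate on the autonomous extended system (S, I, theta).

    The phase obeys theta' = omega for both trajectories, so a phase offset
    is carried unchanged and contributes the exactly-neutral exponent; the
    top exponent is max(top planar exponent, 0) on a torus.
    """
    t = 0.0
    S, I = run_segment(t, S0, I0, t_transient, dt, lam, beta, alpha, delta,
                       gamma, omega)
    t = t_transient
    # theta(t) = th0 + omega*t; evaluate forcing of the perturbed copy at its
    # own phase by shifting its time argument
    dth = d0 * u2
    Sp = S + d0 * u0
    Ip = I + d0 * u1
    n_ren = int(round(t_total / renorm_dt))
    hist = np.empty(n_ren)
    acc = 0.0
    for k in range(n_ren):
        n = int(round(renorm_dt / dt))
        h = renorm_dt / n
        for _ in range(n):
            S, I = _rk4_step(t, S, I, h, lam, beta, alpha, delta, gamma, omega)
            Sp, Ip = _rk4_step(t + dth / omega, Sp, Ip, h, lam, beta, alpha,
                               delta, gamma, omega)
            t += h
        d = math.sqrt((Sp - S) ** 2 + (Ip - I) ** 2 + dth * dth)
        acc += math.log(d / d0)
        hist[k] = acc / ((k + 1) * renorm_dt)
        scale = d0 / d
        Sp = S + (Sp - S) * scale
        Ip = I + (Ip - I) * scale
        dth = dth * scale
    return hist


@njit(cache=False)
def stroboscopic_points(S0, I0, t0, n_transient, n_kept, period, dt,
                        lam, beta, alpha, delta, gamma, omega):
    """Sample (S, I) once per forcing period, discarding transient periods."""
    t = t0
    S, I = S0, I0
    n = int(round(period / dt))
    h = period / n
    for _ in range(n_transient):
        for _ in range(n):
            S, I = _rk4_step(t, S, I, h, lam, beta, alpha, delta, gamma, omega)
            t += h
    out = np.empty((n_kept, 2))
    for k in range(n_kept):
        for _ in range(n):
            S, I = _rk4_step(t, S, I, h, lam, beta, alpha, delta, gamma, omega)
            t += h
        out[k, 0] = S
        out[k, 1] = I
    return out
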