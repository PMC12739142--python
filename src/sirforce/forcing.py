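"""Seasonal forcing of the transmission rate.

The time-dependent transmission rate is ``beta_gamma(t) = beta * (1 + gamma *
psi(omega * t))`` where ``psi`` is a smooth periodic profile.  Admissible
profiles are at least C^3, T-periodic, give the forced rate a positive period
mean, and possess at least two nondegenerate critical points per period.  The
default profile is ``psi(x) = 1 + cos(x)``: smooth, 2*pi-periodic,
nonnegative, with exactly two nondegenerate critical points per period and a
period mean of ``beta * (1 + gamma) > 0``.  Alternative profiles plug in via
:class:`ForcingSpec`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .params import ReducedParams

#: registry key of the profile the fast (compiled) integrators understand
DEFAULT_PROFILE = "one_plus_cos"


def _one_plus_cos(x):
    return 1.0 + np.cos(x)


@dataclass(frozen=True)
class ForcingSpec:
    """Periodic forcing profile psi with its own period.

    ``psi`` consumes a phase angle; in the non-autonomous form it is evaluated
    at ``omega * t``, in the autonomous extended form at the phase variable
    ``theta``.
    """

    psi: Callable[[np.ndarray], np.ndarray] = field(default=_one_plus_cos)
    period_T: float = 2.0 * math.pi
    name: str = DEFAULT_PROFILE

    @classmethod
    def one_plus_cos(cls) -> "ForcingSpec":
        return cls()

    @property
    def is_default_profile(self) -> bool:
        return self.name == DEFAULT_PROFILE


DEFAULT_FORCING = ForcingSpec()


@dataclass(frozen=True)
class ForcingReport:
    """Outcome of the admissibility checks for a forcing profile."""

    periodic: bool
    positive_mean: bool
    n_critical_points: int
    critical_points_ok: bool

    @property
    def ok(self) -> bool:
        return self.periodic and self.positive_mean and self.critical_points_ok


def validate_forcing(forcing: ForcingSpec, params: ReducedParams,
                     n_grid: int = 4096, tol: float = 1e-8) -> ForcingReport:
    """Check a forcing profile against the admissibility hypotheses.

    Numerically verifies T-periodicity (endpoint match), positivity of the
    period mean of ``beta_gamma``, and counts sign changes of the numerical
    derivative of psi that carry a nonzero second derivative (nondegenerate
    critical points); at least two per period are required.

    Raises
    ------
    ValueError
        If psi evaluates to non-finite values on the test grid.
    """
    T = forcing.period_T
    x = np.linspace(0.0, T, n_grid, endpoint=False)
    vals = np.asarray(forcing.psi(x), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("forcing profile produced non-finite values")

    endpoint_gap = abs(float(np.asarray(forcing.psi(0.0)))
                       - float(np.asarray(forcing.psi(T))))
    scale = max(1.0, float(np.max(np.abs(vals))))
    periodic = endpoint_gap < tol * scale

    # period mean of beta_gamma = beta * (1 + gamma * mean(psi))
    mean_rate = params.beta * (1.0 + params.gamma * float(np.mean(vals)))
    positive_mean = mean_rate > 0.0

    h = T / n_grid
    # periodic central differences (the grid covers one full period)
    dpsi = (np.roll(vals, -1) - np.roll(vals, 1)) / (2.0 * h)
    d2psi = (np.roll(vals, -1) - 2.0 * vals + np.roll(vals, 1)) / h ** 2
    sign = np.sign(dpsi)
    # count cyclic sign changes of the derivative, skipping exact zeros at
    # grid points that land on the critical point itself
    pos = np.nonzero(sign != 0)[0]
    d2_scale = max(float(np.max(np.abs(d2psi))), 1e-300)
    n_crit = 0
    if pos.size >= 2:
        sn = sign[pos]
        nxt = np.roll(pos, -1)
        for i, j in zip(range(pos.size), np.roll(np.arange(pos.size), -1)):
            if sn[i] * sn[j] < 0:
                # curvature at the crossing must be nonzero (nondegenerate)
                mid = (pos[i] + (nxt[i] if nxt[i] > pos[i]
                                 else nxt[i] + n_grid)) // 2 % n_grid
                if abs(d2psi[mid]) > 1e-6 * d2_scale:
                    n_crit += 1

    return ForcingReport(periodic=periodic, positive_mean=positive_mean,
                         n_critical_points=n_crit,
                         critical_points_ok=n_crit >= 2)
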