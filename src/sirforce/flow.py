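"""Trajectory integration, invariant-region checks, and limit-cycle tools.

Integration uses an adaptive high-order scipy solver with tight default
tolerances (rtol 1e-8, atol 1e-10).  Limit cycles of the unforced planar
system are located from a Poincare section fixed at ``S = S*`` with downward
crossings (``S' < 0``): the endemic equilibrium lies strictly inside the
cycle, so the section is transverse near it.  The cycle's stability is
summarized by the nontrivial Floquet multiplier, obtained as the derivative
of the one-dimensional return map in I by central finite differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import endemic_equilibrium
from .forcing import DEFAULT_FORCING, ForcingSpec
from .model import rhs_full, rhs_reduced
from .params import FullParams, ReducedParams

logger = logging.getLogger(__name__)

RTOL = 1e-8
ATOL = 1e-10

Params = Union[FullParams, ReducedParams]


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of the full or reduced system."""

    t: np.ndarray
    y: np.ndarray                # shape (n_samples, dim)
    params: Params
    rtol: float
    atol: float
    solver: str = "RK45"


@dataclass(frozen=True)
class LimitCycle:
    """One-period characterization of an attracting periodic orbit."""

    period: float
    orbit_t: np.ndarray
    orbit: np.ndarray            # (n, 2) closed curve over one period
    s_min: float
    s_max: float
    i_min: float
    i_max: float
    floquet: float               # modulus of the nontrivial multiplier
    closure_gap: float


@dataclass(frozen=True)
class CycleSearch:
    """Outcome of the Poincare-section cycle search."""

    status: str                  # "cycle" | "equilibrium" | "undecided"
    cycle: Optional[LimitCycle] = None


def _rhs(params: Params, forcing: ForcingSpec):
    if isinstance(params, FullParams):
        return lambda t, x: rhs_full(t, np.maximum(x, 0.0), params, forcing)
    return lambda t, x: rhs_reduced(t, np.maximum(x, 0.0), params, forcing)


def integrate(params: Params, x0: Sequence[float], t_span: tuple[float, float],
              t_eval: Optional[np.ndarray] = None,
              forcing: ForcingSpec = DEFAULT_FORCING,
              rtol: float = RTOL, atol: float = ATOL,
              method: str = "RK45") -> Trajectory:
    """Integrate the full (3-state) or reduced (2-state) system.

    States are clipped to zero only below 1e-14 (round-off), with a logged
    warning; larger negative excursions raise.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError(f"initial state must be nonnegative, got {x0}")
    sol = solve_ivp(_rhs(params, forcing), t_span, x0, t_eval=t_eval,
                    rtol=rtol, atol=atol, method=method, dense_output=False)
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1]}: {sol.message}; "
            f"last state {sol.y[:, -1]}")
    y = sol.y.T.copy()
    tiny = (y < 0) & (y > -1e-14)
    if np.any(tiny):
        logger.warning("clipped %d round-off-negative samples to zero",
                       int(np.count_nonzero(tiny)))
        y[tiny] = 0.0
    return Trajectory(t=sol.t, y=y, params=params, rtol=rtol, atol=atol,
                      solver=method)


def integrate_ensemble(params: FullParams, x0: np.ndarray, t_end: float,
                       n_samples: int = 200, rtol: float = 1e-8,
                       atol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many full-system copies in one vectorized solver call.

    Parameters are shared; ``x0`` has shape (n, 3).  Returns ``(t, Y)`` with
    ``Y`` of shape (n_samples, n, 3).  Used for invariant-region sweeps where
    per-trajectory adaptive calls would dominate runtime.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.shape[0]

    def rhs(t, z):
        x = z.reshape(n, 3)
        S, I, R = x[:, 0], x[:, 1], x[:, 2]
        bg = params.beta * (1.0 + params.gamma *
                            DEFAULT_FORCING.psi(params.omega * t)) \
            if params.gamma > 0 else params.beta
        inc = bg * S * I * I
        dS = params.lam - inc - (params.a_raw + params.mu) * S
        dI = inc + params.a_raw * S - (params.g + params.mu) * I
        dR = params.g * I - params.mu * R
        return np.column_stack([dS, dI, dR]).ravel()

    t_eval = np.linspace(0.0, t_end, n_samples)
    sol = solve_ivp(rhs, (0.0, t_end), x0.ravel(), t_eval=t_eval,
                    rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeError(f"ensemble integration failed: {sol.message}")
    return sol.t, sol.y.T.reshape(n_samples, n, 3)


def _section_event(S_star: float):
    def event(t, x):
        return x[0] - S_star
    event.direction = -1.0       # downward crossings only (S decreasing)
    event.terminal = False
    return event


def _poincare_crossings(params: ReducedParams, x0, t_max: float,
                        S_star: float, rtol: float, atol: float):
    """All downward S = S* crossings of one trajectory: (times, states)."""
    sol = solve_ivp(lambda t, x: rhs_reduced(t, np.maximum(x, 0.0),
                                             params.unforced()),
                    (0.0, t_max), np.asarray(x0, dtype=float),
                    events=_section_event(S_star), rtol=rtol, atol=atol,
                    method="RK45", dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t_events[0], sol.y_events[0], sol.y[:, -1]


def find_limit_cycle(params: ReducedParams, transient: float = 2000.0,
                     horizon: float = 5000.0, tol: float = 1e-7,
                     min_distance: float = 1e-3,
                     rtol: float = RTOL, atol: float = ATOL,
                     x0: Optional[Sequence[float]] = None,
                     floquet_step: float = 1e-6) -> CycleSearch:
    """Search for an attracting limit cycle of the unforced planar system.

    Integrates past a transient from a point offset from the equilibrium,
    then follows successive downward crossings of the section ``S = S*``.  A
    cycle is reported when the crossing states converge (successive gap below
    ``tol``) to a point bounded away from the equilibrium (``> min_distance``
    in I); convergence onto the equilibrium reports ``equilibrium``; anything
    else is ``undecided``.
    """
    P = endemic_equilibrium(params)
    S_star, I_star = P.S_star, P.I_star
    if x0 is None:
        x0 = (S_star + 0.1, I_star)

    tr = integrate(params.unforced(), x0, (0.0, transient),
                   t_eval=np.array([0.0, transient]), rtol=rtol, atol=atol)
    x_start = tr.y[-1]
    if np.linalg.norm(x_start - P.point) < 1e-8:
        return CycleSearch(status="equilibrium")

    times, states, x_last = _poincare_crossings(
        params, x_start, horizon - transient, S_star, rtol, atol)
    if len(times) < 2:
        near_eq = np.linalg.norm(x_last - P.point) < 1e-5
        return CycleSearch(status="equilibrium" if near_eq else "undecided")

    I_seq = states[:, 1]
    gaps = np.abs(np.diff(I_seq))
    converged = np.nonzero(gaps < tol)[0]
    if converged.size == 0:
        if abs(I_seq[-1] - I_star) < min_distance:
            return CycleSearch(status="equilibrium")
        return CycleSearch(status="undecided")
    k = converged[0]
    I_c = I_seq[k + 1]
    if abs(I_c - I_star) <= min_distance:
        return CycleSearch(status="equilibrium")
    period = times[k + 1] - times[k]

    cycle = _characterize_cycle(params, S_star, I_c, period, rtol, atol,
                                floquet_step)
    return CycleSearch(status="cycle", cycle=cycle)


def _return_map(params: ReducedParams, S_star: float, I: float,
                t_guess: float, rtol: float, atol: float) -> tuple[float, float]:
    """One application of the Poincare return map from (S*, I)."""
    times, states, _ = _poincare_crossings(
        params, (S_star, I), 3.0 * t_guess, S_star, rtol, atol)
    # starting on the section, the solver reports the departure point as an
    # event at t ~ 0; keep only genuine returns
    keep = times > 0.1 * t_guess
    times, states = times[keep], states[keep]
    if len(times) == 0:
        raise RuntimeError("return map: no section crossing found")
    return float(states[0, 1]), float(times[0])


def _characterize_cycle(params: ReducedParams, S_star: float, I_c: float,
                        period_guess: float, rtol: float, atol: float,
                        floquet_step: float) -> LimitCycle:
    # polish the fixed point with two more return-map applications
    I_fix, period = I_c, period_guess
    for _ in range(2):
        I_fix, period = _return_map(params, S_star, I_fix, period, rtol, atol)

    n = 2000
    t_eval = np.linspace(0.0, period, n)
    orbit_tr = integrate(params.unforced(), (S_star, I_fix), (0.0, period),
                         t_eval=t_eval, rtol=rtol, atol=atol)
    orbit = orbit_tr.y
    closure_gap = float(np.linalg.norm(orbit[-1] - orbit[0]))

    def refined_extremum(values: np.ndarray, sign: float) -> float:
        # quadratic interpolation of the discrete maximum of sign*values
        w = sign * values
        j = int(np.argmax(w))
        if 0 < j < n - 1:
            y0, y1, y2 = w[j - 1], w[j], w[j + 1]
            denom = y0 - 2.0 * y1 + y2
            if denom != 0:
                return sign * float(y1 - (y2 - y0) ** 2 / (8.0 * denom))
        return float(values[j])

    s_max = refined_extremum(orbit[:, 0], +1.0)
    s_min = refined_extremum(orbit[:, 0], -1.0)
    i_max = refined_extremum(orbit[:, 1], +1.0)
    i_min = refined_extremum(orbit[:, 1], -1.0)

    h = max(floquet_step, floquet_step * abs(I_fix))
    up, _ = _return_map(params, S_star, I_fix + h, period, rtol, atol)
    dn, _ = _return_map(params, S_star, I_fix - h, period, rtol, atol)
    floquet = abs((up - dn) / (2.0 * h))

    return LimitCycle(period=period, orbit_t=t_eval, orbit=orbit,
                      s_min=s_min, s_max=s_max, i_min=i_min, i_max=i_max,
                      floquet=floquet, closure_gap=closure_gap)


@dataclass(frozen=True)
class AmplitudeScaling:
    """Fit of squared cycle amplitude against distance from onset."""

    betas: np.ndarray
    amplitudes: np.ndarray       # I_max - I_star per beta
    slope: float
    intercept: float
    r_squared: float


def amplitude_scaling(params: ReducedParams, betas: Sequence[float],
                      beta1: float, transient: float = 3000.0,
                      horizon: float = 9000.0) -> AmplitudeScaling:
    """Near-onset Hopf scaling check: amplitude^2 grows linearly in beta - beta1.

    Every beta in the window must yield a detected cycle; a near-linear fit
    (R^2 >= 0.95) of ``(I_max - I*)^2`` against ``beta - beta1`` certifies the
    supercritical square-root amplitude law.
    """
    betas = np.asarray(betas, dtype=float)
    I_star = endemic_equilibrium(params).I_star
    amps = []
    for b in betas:
        p = params.with_beta(float(b))
        search = find_limit_cycle(p, transient=transient, horizon=horizon,
                                  x0=(endemic_equilibrium(p).S_star + 0.05,
                                      I_star))
        if search.status != "cycle":
            raise RuntimeError(
                f"no limit cycle detected at beta={b} (status={search.status})")
        amps.append(search.cycle.i_max - I_star)
    amps = np.asarray(amps)
    x = betas - beta1
    y = amps ** 2
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    return AmplitudeScaling(betas=betas, amplitudes=amps, slope=float(slope),
                            intercept=float(intercept), r_squared=r2)


def bifurcation_diagram(params: ReducedParams, betas: Sequence[float],
                        transient: float = 3000.0, window: float = 500.0,
                        amp_tol: float = 1e-6,
                        rtol: float = RTOL, atol: float = ATOL):
    """Post-transient I extrema of the attractor per beta (unforced system).

    For each beta the trajectory is run past a transient and the extrema of I
    over a sampling window are recorded; where the attractor is the
    equilibrium both extrema collapse onto ``I* = lam/delta`` (independent of
    beta).  The band where ``i_max > i_min`` approximates the open interval
    between the Hopf thresholds within grid resolution.  Returns a pandas
    DataFrame with columns beta, i_min, i_max, i_star, cycle.
    """
    import pandas as pd

    rows = []
    for b in betas:
        p = params.with_beta(float(b)).unforced()
        P = endemic_equilibrium(p)
        tr = integrate(p, (P.S_star + 0.1, P.I_star), (0.0, transient),
                       t_eval=np.array([0.0, transient]), rtol=rtol, atol=atol)
        t_eval = np.linspace(0.0, window, 4000)
        tr2 = integrate(p, tr.y[-1], (0.0, window), t_eval=t_eval,
                        rtol=rtol, atol=atol)
        i_min, i_max = float(tr2.y[:, 1].min()), float(tr2.y[:, 1].max())
        has_cycle = (i_max - i_min) > amp_tol
        if not has_cycle:
            i_min = i_max = P.I_star
        rows.append({"beta": float(b), "i_min": i_min, "i_max": i_max,
                     "i_star": P.I_star, "cycle": has_cycle})
    return pd.DataFrame(rows)
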