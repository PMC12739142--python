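"""Parameter records for the forced SIR model with nonlinear incidence.

Two parameterizations are supported.  The *full* record carries the raw
demographic/epidemiological rates (inflow ``lam``, contact transmission
``beta``, environmental transmission ``a_raw``, cure rate ``g``, death rate
``mu``).  Because the susceptible and infective equations decouple from the
recovered class, the model is usually analyzed in a *reduced* two-dimensional
form in which the environmental rate and the death rate are absorbed into a
single loss rate ``alpha = a_raw + mu`` and the infective loss rate is
``delta = g + mu``.  Records validate at construction so the right-hand sides
stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator


class ParameterError(ValueError):
    """A model parameter violates its admissibility constraint."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise ParameterError(message)


@dataclass(frozen=True)
class ReducedParams:
    """Parameters of the reduced (S, I) system.

    Attributes
    ----------
    lam : float
        Inflow rate of susceptibles (individuals / time).
    beta : float
        Direct-contact transmission coefficient of the ``beta * S * I**2``
        incidence term (unforced value).
    alpha : float
        Combined loss rate of susceptibles: environmental transmission plus
        death rate (time**-1).
    delta : float
        Combined loss rate of infectives: cure plus death rate (time**-1).
    gamma : float
        Seasonal forcing amplitude (dimensionless, >= 0; 0 = unforced).
    omega : float
        Forcing angular frequency (radians / time). Must be positive whenever
        ``gamma > 0``.
    """

    lam: float
    beta: float
    alpha: float
    delta: float
    gamma: float = 0.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        _require(self.lam > 0, f"lam must be positive, got {self.lam}")
        _require(self.beta > 0, f"beta must be positive, got {self.beta}")
        _require(self.alpha > 0, f"alpha must be positive, got {self.alpha}")
        _require(self.delta > 0, f"delta must be positive, got {self.delta}")
        _require(self.gamma >= 0, f"gamma must be nonnegative, got {self.gamma}")
        if self.gamma > 0:
            _require(self.omega > 0,
                     f"omega must be positive when gamma > 0, got {self.omega}")

    def with_beta(self, beta: float) -> "ReducedParams":
        return replace(self, beta=beta)

    def unforced(self) -> "ReducedParams":
        return replace(self, gamma=0.0)

    def __iter__(self) -> Iterator[float]:
        yield from (self.lam, self.beta, self.alpha, self.delta,
                    self.gamma, self.omega)


@dataclass(frozen=True)
class FullParams:
    """Parameters of the full (S, I, R) system before absorption of mu.

    ``a_raw`` is the environmental (viral-source) transmission rate; ``g`` the
    cure rate; ``mu`` the death rate.  The reduced loss rates are derived as
    ``alpha = a_raw + mu`` and ``delta = g + mu``.
    """

    lam: float
    beta: float
    a_raw: float
    g: float
    mu: float
    gamma: float = 0.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        for name in ("lam", "beta", "a_raw", "g", "mu"):
            value = getattr(self, name)
            _require(value > 0, f"{name} must be positive, got {value}")
        _require(self.gamma >= 0, f"gamma must be nonnegative, got {self.gamma}")
        if self.gamma > 0:
            _require(self.omega > 0,
                     f"omega must be positive when gamma > 0, got {self.omega}")

    @property
    def alpha(self) -> float:
        """Reduced susceptible loss rate a_raw + mu."""
        return self.a_raw + self.mu

    @property
    def delta(self) -> float:
        """Reduced infective loss rate g + mu (always exceeds mu)."""
        return self.g + self.mu

    def reduced(self) -> ReducedParams:
        """Absorb mu into the loss rates and drop the recovered class."""
        return ReducedParams(lam=self.lam, beta=self.beta, alpha=self.alpha,
                             delta=self.delta, gamma=self.gamma,
                             omega=self.omega)
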