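"""Named parameter presets for the reference scenarios.

All presets share the base triple (lam, alpha, delta) = (0.9, 0.1, 1.1), for
which the Hopf thresholds are beta_1 ~ 0.243153 and beta_2 ~ 1.101291.
Transmission-rate expressions such as ``(beta1+beta2)/2`` are resolved
through the closed-form thresholds when the preset is built, so every
scenario carries a concrete numeric beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from .equilibrium import hopf_thresholds
from .forcing import DEFAULT_FORCING, ForcingSpec
from .params import ReducedParams

BASE = dict(lam=0.9, alpha=0.1, delta=1.1)


@dataclass(frozen=True)
class Scenario:
    """A fully resolved, runnable parameter scenario."""

    name: str
    params: ReducedParams
    forcing: ForcingSpec = DEFAULT_FORCING
    run: tuple[str, ...] = ("equilibria",)
    options: dict = field(default_factory=dict)
    beta_expression: str = "beta"


def _beta(expr: str) -> float:
    th = hopf_thresholds(ReducedParams(beta=1.0, **BASE))
    table: dict[str, Callable[[], float]] = {
        "(beta1+beta2)/2": lambda: (th.beta1 + th.beta2) / 2.0,
        "beta1-0.1": lambda: th.beta1 - 0.1,
        "beta2+0.1": lambda: th.beta2 + 0.1,
    }
    return table[expr]()


_REGISTRY: dict[str, dict] = {
    "fig2": dict(beta="(beta1+beta2)/2", gamma=0.0, omega=1.0,
                 run=("simulate", "cycle")),
    "fig4i": dict(beta="beta1-0.1", gamma=0.0, omega=1.0,
                  run=("equilibria", "cycle")),
    "fig4ii": dict(beta="(beta1+beta2)/2", gamma=0.0, omega=1.0,
                   run=("equilibria", "cycle")),
    "fig4iii": dict(beta="beta2+0.1", gamma=0.0, omega=1.0,
                    run=("equilibria", "cycle")),
    "fig7": dict(beta="(beta1+beta2)/2", gamma=0.0, omega=0.1,
                 run=("section", "lle")),
    "fig8a": dict(beta="(beta1+beta2)/2", gamma=0.0, omega=0.1,
                  run=("section", "lle", "classify")),
    "fig8b": dict(beta="(beta1+beta2)/2", gamma=0.001, omega=0.5,
                  run=("section", "lle", "classify")),
    "fig8c": dict(beta="(beta1+beta2)/2", gamma=0.001, omega=1.0,
                  run=("section", "lle", "classify")),
    "fig8d": dict(beta="(beta1+beta2)/2", gamma=0.001, omega=1.5,
                  run=("section", "lle", "classify")),
    "fig8e": dict(beta="(beta1+beta2)/2", gamma=0.001, omega=5.0,
                  run=("section", "lle", "classify")),
}


def preset_names() -> list[str]:
    return sorted(_REGISTRY)


def preset(name: str) -> Scenario:
    """Build the named scenario with beta expressions resolved numerically."""
    try:
        spec = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
    params = ReducedParams(beta=_beta(spec["beta"]), gamma=spec["gamma"],
                           omega=spec["omega"], **BASE)
    return Scenario(name=name, params=params, run=spec["run"],
                    beta_expression=spec["beta"])
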