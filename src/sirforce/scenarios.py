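"""Reproducible scenario runs: config round-trip, dispatch, result bundles.

A scenario bundles a parameter record, a forcing profile and a list of
operations.  ``run_scenario`` executes the operations, writes machine-readable
tables (CSV/JSON) plus optional figures into an output directory, and records
a manifest with every resolved parameter, tolerance and the seed, so results
are auditable and reruns with the same seed produce byte-identical tables.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .chaos import attractor_classify, largest_lyapunov, stroboscopic_section
from .equilibrium import endemic_equilibrium, equilibrium_report, hopf_thresholds
from .flow import bifurcation_diagram, find_limit_cycle, integrate
from .hopf import hopf_report
from .params import ReducedParams
from .presets import Scenario

logger = logging.getLogger(__name__)

EXIT_OK, EXIT_VALIDATION, EXIT_NUMERICAL = 0, 2, 3


def scenario_to_dict(s: Scenario) -> dict:
    return {
        "name": s.name,
        "params": {"lam": s.params.lam, "beta": s.params.beta,
                   "alpha": s.params.alpha, "delta": s.params.delta,
                   "gamma": s.params.gamma, "omega": s.params.omega},
        "forcing": {"psi": s.forcing.name, "period_T": s.forcing.period_T},
        "run": {"ops": list(s.run), "options": dict(s.options)},
        "beta_expression": s.beta_expression,
    }


def scenario_from_dict(d: dict) -> Scenario:
    params = ReducedParams(**d["params"])
    return Scenario(name=d["name"], params=params,
                    run=tuple(d["run"]["ops"]),
                    options=dict(d["run"].get("options", {})),
                    beta_expression=d.get("beta_expression", "beta"))


def save_config(s: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(s), sort_keys=True))


def load_config(path) -> Scenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))


def _write_csv(df, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g", lineterminator="\n")


def _phase_plot(traj, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(traj[:, 0], traj[:, 1], lw=0.7)
    ax.set_xlabel("S")
    ax.set_ylabel("I")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_scenario(scenario: Scenario, out_dir, seed: int = 42,
                 make_plots: bool = True) -> dict:
    """Execute a scenario's operations and write a result bundle.

    Returns the in-memory results keyed by operation name; on a stage
    failure the bundle still contains the completed stages plus a failure
    log, and the exception is re-raised after writing.
    """
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = scenario.params
    results: dict = {}
    stages: list[dict] = []
    failure: Optional[str] = None

    try:
        for op in scenario.run:
            t0 = time.perf_counter()
            if op == "equilibria":
                rep = equilibrium_report(params)
                results[op] = rep
                pd.DataFrame([{
                    "S_star": rep["S_star"], "I_star": rep["I_star"],
                    "trace": rep["trace"], "determinant": rep["determinant"],
                    "eig_re": rep["eigenvalues"][0].real,
                    "eig_im": abs(np.imag(rep["eigenvalues"][0])),
                    "label": rep["label"],
                }]).pipe(_write_csv, out / "equilibria.csv")
            elif op == "simulate":
                t_end = float(scenario.options.get("t_end", 3000.0))
                P = endemic_equilibrium(params)
                t_eval = np.linspace(0.0, t_end, 6000)
                tr = integrate(params, (P.S_star + 0.1, P.I_star),
                               (0.0, t_end), t_eval=t_eval)
                results[op] = tr
                df = pd.DataFrame({"t": tr.t, "S": tr.y[:, 0], "I": tr.y[:, 1]})
                _write_csv(df, out / "trajectory.csv")
                if make_plots:
                    _phase_plot(tr.y, out / "phase_portrait.png")
            elif op == "cycle":
                search = find_limit_cycle(params)
                results[op] = search
                info = {"status": search.status}
                if search.cycle is not None:
                    c = search.cycle
                    info.update(period=c.period, i_min=c.i_min, i_max=c.i_max,
                                s_min=c.s_min, s_max=c.s_max,
                                floquet=c.floquet, closure_gap=c.closure_gap)
                    _write_csv(pd.DataFrame({"t": c.orbit_t,
                                             "S": c.orbit[:, 0],
                                             "I": c.orbit[:, 1]}),
                               out / "cycle_orbit.csv")
                (out / "cycle.json").write_text(json.dumps(info, indent=2))
            elif op == "hopf":
                reports = [hopf_report(params, b) for b in ("lower", "upper")]
                results[op] = reports
                (out / "hopf.json").write_text(json.dumps(
                    [r.__dict__ for r in reports], indent=2))
            elif op == "diagram":
                betas = scenario.options.get(
                    "betas", np.linspace(0.05, 1.4, 60))
                df = bifurcation_diagram(params, betas)
                results[op] = df
                _write_csv(df, out / "diagram.csv")
            elif op == "section":
                sec = stroboscopic_section(params)
                results[op] = sec
                df = pd.DataFrame(sec.points, columns=["S", "I"])
                df.insert(0, "k", np.arange(len(df)))
                _write_csv(df, out / "section.csv")
                if make_plots:
                    _phase_plot(sec.points, out / "section.png")
            elif op == "lle":
                est = largest_lyapunov(params, seed=seed)
                results[op] = est
                (out / "lle.json").write_text(json.dumps({
                    "lle": est.lle, "converged": est.converged,
                    "spread": est.spread}, indent=2))
            elif op == "classify":
                lab = attractor_classify(params, lle_kwargs={"seed": seed})
                results[op] = lab
                (out / "attractor.json").write_text(json.dumps({
                    "label": lab.label, "confidence": lab.confidence,
                    "lle": lab.lle}, indent=2))
            else:
                raise ValueError(f"unknown operation {op!r}")
            stages.append({"op": op,
                           "seconds": round(time.perf_counter() - t0, 3)})
            logger.info("stage %s finished in %.2fs", op, stages[-1]["seconds"])
    except Exception as exc:  # noqa: BLE001 - reported in the bundle
        failure = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        th = hopf_thresholds(params)
        manifest = {
            "scenario": scenario_to_dict(scenario),
            "resolved_beta": params.beta,
            "thresholds": {"beta1": th.beta1, "beta2": th.beta2}
            if th.exists else None,
            "seed": seed,
            "version": __version__,
            "stages": stages,
            "failure": failure,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return results
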