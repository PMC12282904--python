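"""Run configuration, pipeline orchestration and CSV writers.

Everything the command line produces goes through here so that results are
scriptable without a shell: ``run_pipeline`` executes the requested
analyses and writes CSV artifacts plus a manifest (inputs, seed, package
version, parameter hash) that fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cea import CEARow, FrontierResult, frontier_analysis, incremental_vs_baseline
from .engine import evaluate_strategy, run_cohort, accrue
from .parameters import ModelParameters, load_parameters, to_dict
from .screening import (
    NO_SCREENING_LABEL,
    ScreeningStrategy,
    strategy_by_label,
    strategy_roster,
)
from .sensitivity import ceac, default_owsa_specs, run_owsa, run_psa

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    params_path: str | Path
    schedule_dir: str | Path | None = None
    synthetic_seed: int | None = None
    strategies: list[str] | None = None  # None = full roster
    run_cea: bool = True
    run_owsa: bool = False
    run_psa: bool = False
    out_dir: str | Path = "results"
    seed: int = 0
    wtp: float | None = None
    psa_iterations: int | None = None
    wtp_grid_max: float = 60000.0
    overrides: dict[str, float] = field(default_factory=dict)


def _parameter_hash(params: ModelParameters) -> str:
    doc = to_dict(params)
    doc["schedules"] = {
        name: sched.values.round(12).tolist()
        for name, sched in sorted(params.schedules.items())
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _load(config: RunConfig) -> ModelParameters:
    if config.schedule_dir is None and config.synthetic_seed is None:
        raise ConfigError(
            "no schedules configured: set schedule_dir or synthetic_seed"
        )
    params = load_parameters(
        config.params_path,
        schedule_path=config.schedule_dir,
        synthetic_seed=config.synthetic_seed,
    )
    for path, value in config.overrides.items():
        params = params.with_value(path, value)
    if config.wtp is not None:
        params.config.wtp_threshold = float(config.wtp)
    if config.psa_iterations is not None:
        params.config.psa_iterations = int(config.psa_iterations)
    return params


def _select_strategies(config: RunConfig) -> list[ScreeningStrategy]:
    if config.strategies is None:
        return strategy_roster()
    chosen = [strategy_by_label(lab) for lab in config.strategies]
    if not any(not s.screens for s in chosen):
        chosen.insert(0, strategy_by_label(NO_SCREENING_LABEL))
    return chosen


def render_cea_tables(
    rows: list[CEARow], frontier: FrontierResult, decimals: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Versus-baseline table and frontier-ladder table, mirroring the
    standard CEA report layout (money and QALYs at two decimals)."""

    def fmt(x):
        return None if x is None else round(x, decimals)

    t4_cols = [
        "strategy", "average_cost_per_person", "incremental_cost",
        "effectiveness_qaly", "incremental_effectiveness", "icer", "status",
    ]
    status_of = {r.strategy: r.status for r in frontier.excluded}
    t4 = pd.DataFrame(
        [
            {
                "strategy": r.strategy,
                "average_cost_per_person": fmt(r.cost),
                "incremental_cost": fmt(r.inc_cost),
                "effectiveness_qaly": fmt(r.qaly),
                "incremental_effectiveness": fmt(r.inc_effect),
                "icer": fmt(r.icer),
                "status": status_of.get(r.strategy, "undominated"),
            }
            for r in rows
        ],
        columns=t4_cols,
    )
    t5 = pd.DataFrame(
        [
            {
                "strategy": r.strategy,
                "average_cost_per_person": fmt(r.cost),
                "incremental_cost": fmt(r.inc_cost),
                "effectiveness_qaly": fmt(r.qaly),
                "incremental_effectiveness": fmt(r.inc_effect),
                "icer": fmt(r.icer),
            }
            for r in frontier.frontier
        ],
        columns=t4_cols[:-1],
    )
    return t4, t5


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analyses; returns the manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        params = _load(config)
        strategies = _select_strategies(config)
        manifest = {
            "package": "htnscreen",
            "version": __version__,
            "seed": config.seed,
            "params_path": str(config.params_path),
            "schedule_dir": None if config.schedule_dir is None else str(config.schedule_dir),
            "synthetic_seed": config.synthetic_seed,
            "overrides": config.overrides,
            "parameter_hash": _parameter_hash(params),
            "strategies": [s.label for s in strategies],
            "artifacts": [],
        }

        def write(name: str, df: pd.DataFrame) -> None:
            path = out_dir / name
            df.to_csv(path, index=False)
            written.append(path)
            manifest["artifacts"].append(name)

        results = [evaluate_strategy(s, params) for s in strategies]
        write(
            "results.csv",
            pd.DataFrame(
                [
                    {"strategy": r.strategy, "cost": r.total_cost, "qaly": r.total_qaly}
                    for r in results
                ]
            ),
        )

        if config.run_cea:
            rows = incremental_vs_baseline(results, NO_SCREENING_LABEL)
            frontier = frontier_analysis(results)
            t4, t5 = render_cea_tables(rows, frontier)
            write("table4.csv", t4)
            write("table5.csv", t5)
            status_of = {r.strategy: r.status for r in frontier.excluded}
            write(
                "ce_plane.csv",
                pd.DataFrame(
                    [
                        {
                            "strategy": r.strategy,
                            "cost": r.total_cost,
                            "qaly": r.total_qaly,
                            "status": status_of.get(r.strategy, "undominated"),
                        }
                        for r in results
                    ]
                ),
            )

        if config.run_owsa:
            specs = default_owsa_specs(params)
            tornado = run_owsa(params, specs, strategies)
            write("tornado.csv", tornado)

        if config.run_psa:
            n_iter = params.config.psa_iterations
            psa = run_psa(params, strategies, n_iter, config.seed)
            long = pd.DataFrame(
                {
                    "iteration": np.repeat(np.arange(n_iter), len(strategies)),
                    "strategy": psa.strategies * n_iter,
                    "cost": psa.costs.ravel(),
                    "qaly": psa.qalys.ravel(),
                }
            )
            write("psa_iterations.csv", long)
            draws = pd.DataFrame(psa.draws, columns=psa.draw_names)
            draws.insert(0, "iteration", np.arange(n_iter))
            write("psa_draws.csv", draws)
            grid = np.linspace(0.0, config.wtp_grid_max, 61)
            write("ceac.csv", ceac(psa, grid))

        manifest_path = out_dir / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def export_trace(strategy: ScreeningStrategy, params: ModelParameters, path: str | Path) -> None:
    """Write the full cohort trace of one strategy as CSV."""
    run_cohort(strategy, params).to_frame().to_csv(path, index=False)
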