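"""Deterministic (one-way) and probabilistic sensitivity analysis.

One-way analysis re-runs the model with each selected parameter at its low
and high range end and reports the outcome swing (tornado data).
Probabilistic analysis assigns a distribution to every parameter with a
95% CI — beta for probabilities and utilities, gamma for costs, relative
risks and rates, fitted by method of moments with the CI width read as
3.92 normal standard deviations — samples all parameters independently,
re-runs every strategy per iteration, and summarizes the iterations as
cost-effectiveness acceptability curves (CEAC), acceptability at a single
willingness-to-pay, and cost-effectiveness-plane scatter data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import nmb
from .engine import StrategyResult, evaluate_strategy
from .parameters import ModelParameters, ParameterValue, sync_derived
from .screening import ScreeningStrategy

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DSASpec:
    """One-way sensitivity range for one parameter (dot-path addressed)."""

    parameter: str
    low: float
    base: float
    high: float

    def __post_init__(self) -> None:
        lo, hi = (self.low, self.high) if self.low <= self.high else (self.high, self.low)
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"{self.parameter}: base {self.base} outside [{self.low}, {self.high}]"
            )


def default_owsa_specs(params: ModelParameters) -> list[DSASpec]:
    """The standard one-way analysis set: the parameters with the largest
    plausible influence (discount rates varied 0.03-0.07, the rest over
    their 95% CIs)."""
    ci_paths = [
        "costs.post_event_incremental.post_stroke",
        "effects.p_stroke_recurrence",
        "utilities.post_mi",
        "utilities.post_stroke",
        "utilities.post_sa",
        "utilities.post_ua",
        "utilities.htn_off_tx",
        "effects.rr_chd_recurrence",
        "screening.specificity",
        "screening.sensitivity",
        "decomposition.stroke_tia",
        "decomposition.chd_fatal",
    ]
    specs = []
    for path in ci_paths:
        pv = params.uncertainty[path]
        specs.append(DSASpec(path, pv.ci_low, pv.value, pv.ci_high))
    for path in ("config.discount_rate_costs", "config.discount_rate_outcomes"):
        specs.append(DSASpec(path, 0.03, params.get_value(path), 0.07))
    return specs


def _outcome(
    params: ModelParameters,
    strategy: ScreeningStrategy,
    baseline: ScreeningStrategy,
    outcome: str,
    wtp: float,
    cache: dict,
) -> float:
    key = strategy.label
    if key not in cache:
        cache[key] = evaluate_strategy(strategy, params)
    res = cache[key]
    if outcome == "cost":
        return res.total_cost
    if outcome == "qaly":
        return res.total_qaly
    if outcome == "nmb":
        if baseline.label not in cache:
            cache[baseline.label] = evaluate_strategy(baseline, params)
        return nmb(res, cache[baseline.label], wtp)
    raise ValueError(f"unknown outcome {outcome!r}")


def run_owsa(
    params: ModelParameters,
    specs: list[DSASpec],
    strategies: list[ScreeningStrategy],
    *,
    baseline: ScreeningStrategy | None = None,
    outcome: str = "nmb",
    wtp: float | None = None,
) -> pd.DataFrame:
    """Tornado table: outcome at each range end for every (parameter,
    strategy), sorted by swing width (descending) within each strategy.

    The default outcome is incremental net monetary benefit versus the
    baseline strategy at the configured willingness to pay.
    """
    if baseline is None:
        baseline = next((s for s in strategies if not s.screens), strategies[0])
    if wtp is None:
        wtp = params.config.wtp_threshold
    for spec in specs:
        params.get_value(spec.parameter)  # raises KeyError when unknown

    base_cache: dict = {}
    rows = []
    for spec in specs:
        caches = {}
        for end, value in (("low", spec.low), ("high", spec.high)):
            varied = sync_derived(params.with_value(spec.parameter, value))
            caches[end] = (varied, {})
        for strat in strategies:
            out_base = _outcome(params, strat, baseline, outcome, wtp, base_cache)
            ends = {}
            for end, (varied, cache) in caches.items():
                ends[end] = _outcome(varied, strat, baseline, outcome, wtp, cache)
            rows.append(
                {
                    "parameter": spec.parameter,
                    "strategy": strat.label,
                    "outcome_low": ends["low"],
                    "outcome_base": out_base,
                    "outcome_high": ends["high"],
                    "width": abs(ends["high"] - ends["low"]),
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["strategy", "width"], ascending=[True, False], kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# probabilistic analysis

BETA_FAMILIES = ("probability", "utility")


@dataclass(frozen=True)
class DistributionAssignment:
    """Sampling distribution for one parameter, method-of-moments fitted."""

    parameter: str
    family: str  # beta | gamma | fixed
    params: dict[str, float] = field(default_factory=dict)

    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        return self.params["value"]

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "beta":
            return float(rng.beta(self.params["alpha"], self.params["beta"]))
        if self.family == "gamma":
            return float(rng.gamma(self.params["shape"], self.params["scale"]))
        return self.params["value"]


def _fit(pv: ParameterValue) -> DistributionAssignment:
    if pv.fixed:
        return DistributionAssignment(pv.name, "fixed", {"value": pv.value})
    mu = pv.value
    sd = (pv.ci_high - pv.ci_low) / 3.92
    if sd <= 0:
        return DistributionAssignment(pv.name, "fixed", {"value": mu})
    if pv.kind in BETA_FAMILIES:
        if not (0.0 < mu < 1.0):
            log.warning("%s: degenerate mean %s for beta; kept fixed", pv.name, mu)
            return DistributionAssignment(pv.name, "fixed", {"value": mu})
        nu = mu * (1.0 - mu) / sd**2 - 1.0
        if nu <= 0:
            log.warning("%s: CI too wide for beta support; kept fixed", pv.name)
            return DistributionAssignment(pv.name, "fixed", {"value": mu})
        return DistributionAssignment(
            pv.name, "beta", {"alpha": mu * nu, "beta": (1.0 - mu) * nu}
        )
    # positive-support quantities: cost, relative risk, rate
    if mu <= 0:
        return DistributionAssignment(pv.name, "fixed", {"value": mu})
    return DistributionAssignment(
        pv.name, "gamma", {"shape": (mu / sd) ** 2, "scale": sd**2 / mu}
    )


def assign_distributions(params: ModelParameters) -> list[DistributionAssignment]:
    """One assignment per scalar parameter; parameters without a CI stay
    fixed."""
    return [_fit(pv) for pv in params.parameter_values()]


@dataclass
class PSAResult:
    iterations: int
    strategies: list[str]
    costs: np.ndarray  # (iterations, strategies)
    qalys: np.ndarray
    draw_names: list[str]
    draws: np.ndarray  # (iterations, sampled parameters)
    seed: int
    n_rejected: int = 0


def _draw_valid(
    assignments: list[DistributionAssignment],
    rng: np.random.Generator,
    max_tries: int = 100,
) -> tuple[dict[str, float], int]:
    """Sample one parameter vector; reject draws that break structural
    invariants (an on-treatment relative risk above one)."""
    rejected = 0
    for _ in range(max_tries):
        draws = {
            a.parameter: a.sample(rng) for a in assignments if a.family != "fixed"
        }
        ok = True
        for path in ("effects.rr_chd_on_treatment", "effects.rr_stroke_on_treatment"):
            if draws.get(path, 0.5) > 1.0:
                ok = False
        if draws.get("effects.rr_chd_recurrence", 2.0) < 1.0:
            ok = False
        if ok:
            return draws, rejected
        rejected += 1
    raise RuntimeError("could not draw a valid parameter vector")


def _apply_draws(params: ModelParameters, draws: dict[str, float]) -> ModelParameters:
    import copy

    from .parameters import _resolve

    out = copy.deepcopy(params)
    for path, value in draws.items():
        _resolve(out, path.split("."), set_to=float(value))
    return sync_derived(out)


def run_psa(
    params: ModelParameters,
    strategies: list[ScreeningStrategy],
    n_iter: int,
    seed: int,
) -> PSAResult:
    """Monte-Carlo parameter uncertainty: per iteration, sample every
    non-fixed parameter, rebuild the model and run every strategy."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    assignments = assign_distributions(params)
    sampled = [a for a in assignments if a.family != "fixed"]
    rng = np.random.default_rng(seed)
    labels = [s.label for s in strategies]
    costs = np.zeros((n_iter, len(strategies)))
    qalys = np.zeros((n_iter, len(strategies)))
    draws_mat = np.zeros((n_iter, len(sampled)))
    names = [a.parameter for a in sampled]
    n_rejected = 0
    for it in range(n_iter):
        draws, rej = _draw_valid(assignments, rng)
        n_rejected += rej
        draws_mat[it] = [draws[name] for name in names]
        p_it = _apply_draws(params, draws)
        for j, strat in enumerate(strategies):
            res = evaluate_strategy(strat, p_it)
            costs[it, j] = res.total_cost
            qalys[it, j] = res.total_qaly
    if n_rejected:
        log.info("PSA: %d rejected parameter vectors resampled", n_rejected)
    return PSAResult(
        iterations=n_iter,
        strategies=labels,
        costs=costs,
        qalys=qalys,
        draw_names=names,
        draws=draws_mat,
        seed=seed,
        n_rejected=n_rejected,
    )


def _winners(psa: PSAResult, wtp: float) -> np.ndarray:
    """Index of the NMB-maximizing strategy per iteration, ties to the
    cheaper strategy."""
    nmb_mat = wtp * psa.qalys - psa.costs
    best = nmb_mat.max(axis=1, keepdims=True)
    tied = nmb_mat >= best - 1e-9
    cost_masked = np.where(tied, psa.costs, np.inf)
    return cost_masked.argmin(axis=1)


def ceac(psa: PSAResult, wtp_grid: list[float] | np.ndarray) -> pd.DataFrame:
    """Probability each strategy maximizes net monetary benefit, per WTP.

    Rows sum to one across strategies at every willingness-to-pay value.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    out = np.zeros((len(wtp_grid), len(psa.strategies)))
    for i, w in enumerate(wtp_grid):
        win = _winners(psa, w)
        for j in range(len(psa.strategies)):
            out[i, j] = np.mean(win == j)
    df = pd.DataFrame(out, columns=psa.strategies)
    df.insert(0, "wtp", wtp_grid)
    return df


def acceptability_at_wtp(psa: PSAResult, wtp: float) -> dict[str, float]:
    """Single-WTP slice of the acceptability curve."""
    row = ceac(psa, [wtp]).iloc[0]
    return {s: float(row[s]) for s in psa.strategies}


def scatter_data(psa: PSAResult, baseline: str) -> dict[str, pd.DataFrame]:
    """Per-strategy incremental (cost, QALY) pairs versus the baseline,
    one point per iteration (the baseline's own points sit at the origin)."""
    if baseline not in psa.strategies:
        raise ValueError(f"baseline {baseline!r} not among PSA strategies")
    jb = psa.strategies.index(baseline)
    out = {}
    for j, s in enumerate(psa.strategies):
        out[s] = pd.DataFrame(
            {
                "delta_cost": psa.costs[:, j] - psa.costs[:, jb],
                "delta_qaly": psa.qalys[:, j] - psa.qalys[:, jb],
            }
        )
    return out
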