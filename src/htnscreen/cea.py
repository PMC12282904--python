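"""Incremental cost-effectiveness analysis.

Given per-strategy lifetime discounted (cost, QALY) pairs this module
produces the comparison-versus-baseline table, the dominance classification
and efficiency frontier with its step-wise ICER ladder, net monetary
benefit, and the optimal strategy at a willingness-to-pay threshold.

Dominance conventions: a strategy is absolutely dominated when some other
strategy has strictly lower cost and at least as many QALYs (weak dominance
folded in; exact cost-and-QALY ties keep the earlier-listed strategy).
Extended dominance removes strategies whose presence breaks the
non-decreasing step-ICER property of the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import StrategyResult

UNDOMINATED = "undominated"
ABSOLUTELY_DOMINATED = "absolutely_dominated"
EXTENDED_DOMINATED = "extended_dominated"


@dataclass(frozen=True)
class CEARow:
    strategy: str
    cost: float
    qaly: float
    inc_cost: float | None = None
    inc_effect: float | None = None
    icer: float | None = None
    status: str = UNDOMINATED


@dataclass(frozen=True)
class FrontierResult:
    """Ordered undominated rows (cost and QALY increasing) with step ICERs;
    ``excluded`` carries the dominated rows with their status."""

    frontier: tuple[CEARow, ...]
    excluded: tuple[CEARow, ...]

    @property
    def labels(self) -> list[str]:
        return [r.strategy for r in self.frontier]


def incremental_vs_baseline(
    results: list[StrategyResult], baseline: str
) -> list[CEARow]:
    """Each strategy's incremental cost/effect and ICER versus one baseline."""
    labels = [r.strategy for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")
    try:
        base = next(r for r in results if r.strategy == baseline)
    except StopIteration:
        raise ValueError(f"baseline {baseline!r} not among results") from None
    rows = []
    for r in results:
        d_cost = r.total_cost - base.total_cost
        d_eff = r.total_qaly - base.total_qaly
        icer = d_cost / d_eff if d_eff > 0 else None
        rows.append(
            CEARow(
                strategy=r.strategy,
                cost=r.total_cost,
                qaly=r.total_qaly,
                inc_cost=d_cost,
                inc_effect=d_eff,
                icer=icer,
            )
        )
    return rows


def frontier_analysis(results: list[StrategyResult]) -> FrontierResult:
    """Dominance classification and the efficiency frontier.

    Strategies are sorted by cost (ties by original order); absolute
    dominance is removed first, then extended dominance by iterative repair
    of step-ICER monotonicity.
    """
    if len(results) < 2:
        rows = tuple(
            CEARow(r.strategy, r.total_cost, r.total_qaly) for r in results
        )
        return FrontierResult(frontier=rows, excluded=())

    order = sorted(range(len(results)), key=lambda i: (results[i].total_cost, i))
    pts = [(results[i].strategy, results[i].total_cost, results[i].total_qaly)
           for i in order]

    status = {}
    for i, (lab_i, c_i, q_i) in enumerate(pts):
        dominated = False
        for j, (lab_j, c_j, q_j) in enumerate(pts):
            if i == j:
                continue
            if (
                (c_j < c_i and q_j >= q_i)
                or (c_j == c_i and q_j > q_i)
                or (c_j == c_i and q_j == q_i and j < i)
            ):
                dominated = True
                break
        status[lab_i] = ABSOLUTELY_DOMINATED if dominated else UNDOMINATED

    survivors = [pt for pt in pts if status[pt[0]] == UNDOMINATED]
    # survivors now strictly increase in both cost and qaly; repair ICERs
    changed = True
    while changed and len(survivors) > 2:
        changed = False
        icers = [
            (survivors[k][1] - survivors[k - 1][1])
            / (survivors[k][2] - survivors[k - 1][2])
            for k in range(1, len(survivors))
        ]
        for k in range(1, len(icers)):
            if icers[k] < icers[k - 1] - 1e-12:
                status[survivors[k][0]] = EXTENDED_DOMINATED
                del survivors[k]
                changed = True
                break

    frontier_rows = []
    prev = None
    for lab, cost, qaly in survivors:
        if prev is None:
            frontier_rows.append(CEARow(lab, cost, qaly))
        else:
            d_cost = cost - prev[1]
            d_eff = qaly - prev[2]
            frontier_rows.append(
                CEARow(lab, cost, qaly, inc_cost=d_cost, inc_effect=d_eff,
                       icer=d_cost / d_eff if d_eff > 0 else None)
            )
        prev = (lab, cost, qaly)

    excluded = tuple(
        CEARow(lab, cost, qaly, status=status[lab])
        for lab, cost, qaly in pts
        if status[lab] != UNDOMINATED
    )
    return FrontierResult(frontier=tuple(frontier_rows), excluded=excluded)


def step_icers(frontier: FrontierResult) -> list[tuple[str, float]]:
    """(strategy, ICER-versus-predecessor) along the frontier, baseline
    excluded."""
    return [(r.strategy, r.icer) for r in frontier.frontier[1:]]


def nmb(result: StrategyResult, baseline: StrategyResult, wtp: float) -> float:
    """Incremental net monetary benefit: wtp * dQALY - dcost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    return wtp * (result.total_qaly - baseline.total_qaly) - (
        result.total_cost - baseline.total_cost
    )


def optimal_at_wtp(frontier: FrontierResult, wtp: float) -> str:
    """Most effective frontier strategy whose step ICER is within the
    willingness to pay (the baseline when none is); equals the NMB argmax
    among frontier strategies, with ties going to the cheaper one."""
    if not frontier.frontier:
        raise ValueError("empty frontier")
    best = frontier.frontier[0].strategy
    for row in frontier.frontier[1:]:
        if row.icer is not None and row.icer <= wtp:
            best = row.strategy
    return best
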