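"""Annual-cycle Markov cohort engine.

Ten persistent states: healthy, hypertension off/on treatment, five
post-event states (MI, stable angina, unstable angina, stroke, TIA) and two
absorbing death states (CVD, non-CVD). CHD and stroke events are
within-cycle chance nodes: event mass is split across fatal and non-fatal
outcomes by the (renormalized) event decomposition in the same cycle, with
the event-year cost and the destination post-state's utility applied in the
event cycle and survivors occupying the post state from the next cycle.

Cycle ordering: screening (when the attained age falls on a round) acts on
start-of-cycle occupancy; non-CVD death competes first within the cycle;
survivors then face event risks; remaining healthy/untreated mass flows
through hypertension incidence and background treatment uptake. No
half-cycle correction is applied: cycle t contributions are divided by
(1 + r)^t, with cycle 0 undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import ModelParameters
from .screening import ScreeningStrategy, apply_screening, is_screening_cycle

# persistent state indices
HEALTHY, HTN_OFF, HTN_ON = 0, 1, 2
POST_MI, POST_SA, POST_UA, POST_STROKE, POST_TIA = 3, 4, 5, 6, 7
DEAD_CVD, DEAD_NONCVD = 8, 9

STATE_NAMES = (
    "healthy",
    "htn_off_tx",
    "htn_on_tx",
    "post_mi",
    "post_sa",
    "post_ua",
    "post_stroke",
    "post_tia",
    "dead_cvd",
    "dead_noncvd",
)
N_STATES = 10

COST_COMPONENTS = (
    "screening",
    "confirmatory",
    "treatment_new",
    "treatment_maintenance",
    "event",
    "death",
    "post_event",
)


class PropagationError(RuntimeError):
    """Negative occupancy or broken mass conservation during a run."""


class ConstructionError(ValueError):
    """Per-cycle probabilities are inconsistent (sum above one)."""


@dataclass
class _Context:
    """Schedules and scalars unpacked once per run for speed."""

    params: ModelParameters

    def __post_init__(self) -> None:
        p = self.params
        entry = p.config.cohort_entry_age
        n = p.config.n_cycles
        ages = np.arange(entry, entry + n)

        def tab(name: str) -> np.ndarray:
            s = p.schedules[name]
            return np.array([s.at(min(a, s.age_max)) for a in ages])

        self.ages = ages
        self.mort = tab("noncvd_death")
        self.chd_h = tab("healthy_chd")
        self.stroke_h = tab("healthy_stroke")
        self.chd_u = tab("untreated_chd")
        self.stroke_u = tab("untreated_stroke")
        self.htn_inc = tab("htn_incidence")
        self.uptake = tab("treatment_uptake")

        eff = p.effects
        self.chd_t = np.clip(self.chd_u * eff.rr_chd_on_treatment, 0, 1)
        self.stroke_t = np.clip(self.stroke_u * eff.rr_stroke_on_treatment, 0, 1)
        self.chd_rec = np.clip(self.chd_h * eff.rr_chd_recurrence, 0, 1)
        self.stroke_rec = eff.p_stroke_recurrence

        self.chd_branch = p.decomposition.chd_branch(p.renormalize)
        self.stroke_branch = p.decomposition.stroke_branch(p.renormalize)

        u = p.utilities
        self.utility = np.array([
            u.healthy, u.htn_off_tx, u.htn_on_tx,
            u.post_mi, u.post_sa, u.post_ua, u.post_stroke, u.post_tia,
            u.dead, u.dead,
        ])
        c = p.costs
        self.post_cost = {
            POST_MI: c.post_event_incremental["post_mi"],
            POST_SA: c.post_event_incremental["post_sa"],
            POST_UA: c.post_event_incremental["post_ua"],
            POST_STROKE: c.post_event_incremental["post_stroke"],
            POST_TIA: c.post_event_incremental["post_tia"],
        }
        self.cv_death = {
            POST_MI: p.post_risks.cv_death_post_mi,
            POST_SA: p.post_risks.cv_death_post_sa,
            POST_UA: p.post_risks.cv_death_post_ua,
            POST_STROKE: p.post_risks.cv_death_post_stroke,
            POST_TIA: p.post_risks.cv_death_post_tia,
        }
        rc = p.config.discount_rate_costs
        ro = p.config.discount_rate_outcomes
        t = np.arange(n)
        self.disc_c = (1.0 + rc) ** -t
        self.disc_o = (1.0 + ro) ** -t


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accruals for one strategy run.

    ``occupancy[t]`` is the start-of-cycle (pre-screening) distribution;
    accruals are flow-based within cycle t (end-of-cycle state utilities,
    event-year costs in the event cycle).
    """

    strategy: str
    ages: np.ndarray
    occupancy: np.ndarray  # (n_cycles, N_STATES)
    cycle_costs: np.ndarray  # undiscounted
    cycle_qalys: np.ndarray
    cycle_costs_disc: np.ndarray
    cycle_qalys_disc: np.ndarray
    cost_components: dict[str, np.ndarray] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.occupancy, columns=list(STATE_NAMES))
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df["cost"] = self.cycle_costs
        df["qaly"] = self.cycle_qalys
        df["cost_disc"] = self.cycle_costs_disc
        df["qaly_disc"] = self.cycle_qalys_disc
        for k, v in self.cost_components.items():
            df[f"cost_{k}"] = v
        return df


@dataclass(frozen=True)
class StrategyResult:
    """Expected lifetime discounted cost and QALY per person."""

    strategy: str
    total_cost: float
    total_qaly: float


def _cycle_step(
    occ: np.ndarray,
    t: int,
    screen_cycle: bool,
    ctx: _Context,
) -> tuple[np.ndarray, dict[str, float], float]:
    """One annual cycle: returns end-of-cycle occupancy, undiscounted cost
    components and undiscounted QALY accrual."""
    p = ctx.params
    pr = p.post_risks
    c = p.costs
    new = np.zeros(N_STATES)
    comp = {k: 0.0 for k in COST_COMPONENTS}

    m = ctx.mort[t]
    inc = ctx.htn_inc[t]
    upt = ctx.uptake[t]

    chd_events = 0.0
    stroke_events = 0.0
    bg_start = 0.0
    scr_start = 0.0

    # start-of-cycle standing costs: ongoing treatment, post-event years
    comp["treatment_maintenance"] = occ[HTN_ON] * c.tx_previous
    comp["post_event"] = sum(occ[s] * ctx.post_cost[s] for s in ctx.post_cost)

    # (mass, p_chd, p_stroke) sub-populations with healthy-state dynamics
    healthy_groups: list[tuple[float, float, float]] = []
    untreated_groups: list[tuple[float, float, float]] = []
    treated_mass = occ[HTN_ON]

    if screen_cycle:
        ho, uo = apply_screening(occ[HEALTHY], occ[HTN_OFF], p)
        comp["screening"] = ho.screening_cost + uo.screening_cost
        comp["confirmatory"] = ho.confirmatory_cost + uo.confirmatory_cost
        healthy_groups.append(
            (ho.not_participating + ho.true_negative, ctx.chd_h[t], ctx.stroke_h[t])
        )
        healthy_groups.append(
            (ho.false_positive,
             pr.event_risk_false_positive_chd, pr.event_risk_false_positive_stroke)
        )
        tp_treat = uo.true_positive * p.screening.uptake_true_positive
        scr_start = tp_treat
        treated_mass += tp_treat
        untreated_groups.append(
            (uo.not_participating, ctx.chd_u[t], ctx.stroke_u[t])
        )
        untreated_groups.append(
            (uo.false_negative,
             pr.event_risk_false_negative_chd, pr.event_risk_false_negative_stroke)
        )
        untreated_groups.append(
            (uo.true_positive - tp_treat,
             pr.event_risk_true_positive_chd, pr.event_risk_true_positive_stroke)
        )
    else:
        healthy_groups.append((occ[HEALTHY], ctx.chd_h[t], ctx.stroke_h[t]))
        untreated_groups.append((occ[HTN_OFF], ctx.chd_u[t], ctx.stroke_u[t]))

    for g, pc, ps in healthy_groups:
        if g > 0 and pc + ps > 1.0 + 1e-9:
            raise ConstructionError(f"healthy event probabilities sum to {pc + ps}")
        dead_nc = g * m
        s = g - dead_nc
        ce, se = s * pc, s * ps
        rest = s - ce - se
        htn = rest * inc
        n_on = htn * upt
        new[HEALTHY] += rest - htn
        new[HTN_OFF] += htn - n_on
        new[HTN_ON] += n_on
        new[DEAD_NONCVD] += dead_nc
        bg_start += n_on
        chd_events += ce
        stroke_events += se

    for g, pc, ps in untreated_groups:
        if g > 0 and pc + ps > 1.0 + 1e-9:
            raise ConstructionError(f"untreated event probabilities sum to {pc + ps}")
        dead_nc = g * m
        s = g - dead_nc
        ce, se = s * pc, s * ps
        rest = s - ce - se
        n_on = rest * upt
        new[HTN_ON] += n_on
        new[HTN_OFF] += rest - n_on
        new[DEAD_NONCVD] += dead_nc
        bg_start += n_on
        chd_events += ce
        stroke_events += se

    g = treated_mass
    dead_nc = g * m
    s = g - dead_nc
    ce, se = s * ctx.chd_t[t], s * ctx.stroke_t[t]
    new[HTN_ON] += s - ce - se
    new[DEAD_NONCVD] += dead_nc
    chd_events += ce
    stroke_events += se

    for st in (POST_MI, POST_SA, POST_UA, POST_STROKE, POST_TIA):
        g = occ[st]
        dead_nc = g * m
        s = g - dead_nc
        cvp = ctx.cv_death[st]
        evp = ctx.chd_rec[t] if st in (POST_MI, POST_SA, POST_UA) else ctx.stroke_rec
        if g > 0 and cvp + evp > 1.0 + 1e-9:
            raise ConstructionError(
                f"post-state {STATE_NAMES[st]} probabilities sum to {cvp + evp}"
            )
        cv = s * cvp
        ev = s * evp
        new[st] += s - cv - ev
        new[DEAD_CVD] += cv
        new[DEAD_NONCVD] += dead_nc
        if st in (POST_MI, POST_SA, POST_UA):
            chd_events += ev
        else:
            stroke_events += ev

    new[DEAD_CVD] += occ[DEAD_CVD]
    new[DEAD_NONCVD] += occ[DEAD_NONCVD]

    # within-cycle event chance nodes
    b = ctx.chd_branch
    new[DEAD_CVD] += chd_events * b["fatal"]
    new[POST_MI] += chd_events * b["mi"]
    new[POST_SA] += chd_events * b["sa"]
    new[POST_UA] += chd_events * b["ua"]
    comp["death"] += chd_events * b["fatal"] * c.death_year["chd"]
    comp["event"] += chd_events * (
        b["mi"] * c.event_year["mi"]
        + b["sa"] * c.event_year["sa"]
        + b["ua"] * c.event_year["ua"]
    )
    sb = ctx.stroke_branch
    new[DEAD_CVD] += stroke_events * sb["fatal"]
    new[POST_STROKE] += stroke_events * sb["nonfatal"]
    new[POST_TIA] += stroke_events * sb["tia"]
    comp["death"] += stroke_events * sb["fatal"] * c.death_year["stroke"]
    comp["event"] += stroke_events * (
        sb["nonfatal"] * c.event_year["stroke"] + sb["tia"] * c.event_year["tia"]
    )

    # treatment initiation: background starters pay the no-screening
    # new-case cost; screen-detected starters pay the with-screening
    # new-case cost net of the contact charge already counted above
    comp["treatment_new"] = bg_start * c.tx_new_no_screen + scr_start * (
        c.tx_new_with_screen - c.screening_contact
    )

    qaly = float(new @ ctx.utility)
    return new, comp, qaly


def transition_row(
    state: int,
    age: int,
    on_screen_cycle: bool,
    params: ModelParameters,
    strategy: ScreeningStrategy | None = None,
) -> np.ndarray:
    """Folded one-cycle transition probabilities from one persistent state.

    Event chance nodes are resolved into their destinations, so the row is
    a distribution over the ten persistent states. On a screening cycle the
    row for healthy / untreated mass includes the screen-outcome splits.
    """
    ctx = _Context(params)
    t = age - params.config.cohort_entry_age
    if t < 0 or t >= params.config.n_cycles:
        raise ValueError(f"age {age} outside the modelled horizon")
    occ = np.zeros(N_STATES)
    occ[state] = 1.0
    row, _, _ = _cycle_step(occ, t, on_screen_cycle, ctx)
    if abs(row.sum() - 1.0) > 1e-9:
        raise ConstructionError(f"transition row sums to {row.sum()}")
    return row


def run_cohort(strategy: ScreeningStrategy, params: ModelParameters) -> CohortTrace:
    """Propagate the cohort for ``n_cycles`` annual cycles."""
    ctx = _Context(params)
    n = params.config.n_cycles
    occupancy = np.zeros((n, N_STATES))
    costs = np.zeros(n)
    qalys = np.zeros(n)
    components = {k: np.zeros(n) for k in COST_COMPONENTS}

    occ = np.zeros(N_STATES)
    h, off, on = params.initial.as_tuple(params.renormalize)
    occ[HEALTHY], occ[HTN_OFF], occ[HTN_ON] = h, off, on

    for t in range(n):
        occupancy[t] = occ
        age = int(ctx.ages[t])
        new, comp, q = _cycle_step(occ, t, is_screening_cycle(strategy, age), ctx)
        if (new < -1e-15).any():
            raise PropagationError(f"negative occupancy at cycle {t}: {new}")
        if abs(new.sum() - occ.sum()) > 1e-12:
            raise PropagationError(
                f"mass not conserved at cycle {t}: {new.sum()} vs {occ.sum()}"
            )
        for k, v in comp.items():
            components[k][t] = v
        costs[t] = sum(comp.values())
        qalys[t] = q
        occ = new

    return CohortTrace(
        strategy=strategy.label,
        ages=ctx.ages,
        occupancy=occupancy,
        cycle_costs=costs,
        cycle_qalys=qalys,
        cycle_costs_disc=costs * ctx.disc_c,
        cycle_qalys_disc=qalys * ctx.disc_o,
        cost_components=components,
    )


def accrue(trace: CohortTrace, params: ModelParameters) -> StrategyResult:
    """Discount and sum the per-cycle accruals of a trace."""
    n = len(trace.cycle_costs)
    t = np.arange(n)
    disc_c = (1.0 + params.config.discount_rate_costs) ** -t
    disc_o = (1.0 + params.config.discount_rate_outcomes) ** -t
    return StrategyResult(
        strategy=trace.strategy,
        total_cost=float(trace.cycle_costs @ disc_c),
        total_qaly=float(trace.cycle_qalys @ disc_o),
    )


def evaluate_strategy(
    strategy: ScreeningStrategy, params: ModelParameters
) -> StrategyResult:
    return accrue(run_cohort(strategy, params), params)


# ---------------------------------------------------------------------------
# microsimulation oracle

@dataclass(frozen=True)
class MicrosimResult(StrategyResult):
    """Monte-Carlo estimate with standard errors of the means."""

    se_cost: float = 0.0
    se_qaly: float = 0.0
    n_individuals: int = 0


def microsim_oracle(
    strategy: ScreeningStrategy,
    params: ModelParameters,
    n_individuals: int,
    seed: int,
) -> MicrosimResult:
    """Individual-level simulation through the identical per-cycle
    probabilities and cost rules; its expectation equals the cohort result.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    ctx = _Context(params)
    p = ctx.params
    pr = p.post_risks
    c = p.costs
    scr = p.screening
    rng = np.random.default_rng(seed)
    n = n_individuals

    h, off, on = p.initial.as_tuple(p.renormalize)
    u0 = rng.random(n)
    state = np.full(n, HTN_ON, dtype=np.int64)
    state[u0 < h] = HEALTHY
    state[(u0 >= h) & (u0 < h + off)] = HTN_OFF

    cost = np.zeros(n)
    qaly = np.zeros(n)
    b = ctx.chd_branch
    sb = ctx.stroke_branch
    chd_fatal, chd_mi = b["fatal"], b["mi"]
    chd_sa = b["sa"]
    str_fatal, str_nonfatal = sb["fatal"], sb["nonfatal"]
    post_chd = (POST_MI, POST_SA, POST_UA)
    event_cost_chd = {POST_MI: c.event_year["mi"], POST_SA: c.event_year["sa"],
                      POST_UA: c.event_year["ua"]}

    for t in range(p.config.n_cycles):
        age = int(ctx.ages[t])
        dc, do = ctx.disc_c[t], ctx.disc_o[t]
        alive = state < DEAD_CVD

        # standing costs on start-of-cycle states
        cost[state == HTN_ON] += c.tx_previous * dc
        for st, pc_cost in ctx.post_cost.items():
            cost[state == st] += pc_cost * dc

        pc = np.zeros(n)
        ps = np.zeros(n)
        cvp = np.zeros(n)
        pc[state == HEALTHY] = ctx.chd_h[t]
        ps[state == HEALTHY] = ctx.stroke_h[t]
        pc[state == HTN_OFF] = ctx.chd_u[t]
        ps[state == HTN_OFF] = ctx.stroke_u[t]
        pc[state == HTN_ON] = ctx.chd_t[t]
        ps[state == HTN_ON] = ctx.stroke_t[t]
        for st in post_chd:
            pc[state == st] = ctx.chd_rec[t]
            cvp[state == st] = ctx.cv_death[st]
        for st in (POST_STROKE, POST_TIA):
            ps[state == st] = ctx.stroke_rec
            cvp[state == st] = ctx.cv_death[st]

        if is_screening_cycle(strategy, age):
            part_h = (state == HEALTHY) & (rng.random(n) < scr.participation_healthy)
            cost[part_h] += c.screening_contact * dc
            fp = part_h & (rng.random(n) >= scr.specificity)
            cost[fp] += c.confirmatory_workup * dc
            pc[fp] = pr.event_risk_false_positive_chd
            ps[fp] = pr.event_risk_false_positive_stroke

            part_u = (state == HTN_OFF) & (rng.random(n) < scr.participation_untreated)
            cost[part_u] += c.screening_contact * dc
            tp = part_u & (rng.random(n) < scr.sensitivity)
            cost[tp] += c.confirmatory_workup * dc
            fn = part_u & ~tp
            pc[fn] = pr.event_risk_false_negative_chd
            ps[fn] = pr.event_risk_false_negative_stroke
            start = tp & (rng.random(n) < scr.uptake_true_positive)
            tp_stay = tp & ~start
            pc[tp_stay] = pr.event_risk_true_positive_chd
            ps[tp_stay] = pr.event_risk_true_positive_stroke
            state[start] = HTN_ON
            pc[start] = ctx.chd_t[t]
            ps[start] = ctx.stroke_t[t]
            cost[start] += (c.tx_new_with_screen - c.screening_contact) * dc

        # non-CVD death competes first
        die_nc = alive & (rng.random(n) < ctx.mort[t])
        surv = alive & ~die_nc

        u = rng.random(n)
        chd_ev = surv & (u < pc)
        stroke_ev = surv & ~chd_ev & (u < pc + ps)
        cv_die = surv & ~chd_ev & ~stroke_ev & (u < pc + ps + cvp)
        stay = surv & ~chd_ev & ~stroke_ev & ~cv_die

        # hypertension incidence / background uptake among stayers
        u3 = rng.random(n)
        h_stay = stay & (state == HEALTHY)
        to_on_h = h_stay & (u3 < ctx.htn_inc[t] * ctx.uptake[t])
        to_off_h = h_stay & ~to_on_h & (u3 < ctx.htn_inc[t])
        off_stay = stay & (state == HTN_OFF)
        to_on_u = off_stay & (u3 < ctx.uptake[t])
        state[to_on_h | to_on_u] = HTN_ON
        state[to_off_h] = HTN_OFF
        cost[to_on_h | to_on_u] += c.tx_new_no_screen * dc

        # event decomposition
        u4 = rng.random(n)
        ev_fatal_c = chd_ev & (u4 < chd_fatal)
        ev_mi = chd_ev & ~ev_fatal_c & (u4 < chd_fatal + chd_mi)
        ev_sa = chd_ev & ~ev_fatal_c & ~ev_mi & (u4 < chd_fatal + chd_mi + chd_sa)
        ev_ua = chd_ev & ~ev_fatal_c & ~ev_mi & ~ev_sa
        ev_fatal_s = stroke_ev & (u4 < str_fatal)
        ev_stroke = stroke_ev & ~ev_fatal_s & (u4 < str_fatal + str_nonfatal)
        ev_tia = stroke_ev & ~ev_fatal_s & ~ev_stroke

        state[ev_fatal_c | ev_fatal_s] = DEAD_CVD
        cost[ev_fatal_c] += c.death_year["chd"] * dc
        cost[ev_fatal_s] += c.death_year["stroke"] * dc
        for mask, st in ((ev_mi, POST_MI), (ev_sa, POST_SA), (ev_ua, POST_UA)):
            state[mask] = st
            cost[mask] += event_cost_chd[st] * dc
        state[ev_stroke] = POST_STROKE
        cost[ev_stroke] += c.event_year["stroke"] * dc
        state[ev_tia] = POST_TIA
        cost[ev_tia] += c.event_year["tia"] * dc

        state[cv_die] = DEAD_CVD
        state[die_nc] = DEAD_NONCVD

        qaly += ctx.utility[state] * do

    return MicrosimResult(
        strategy=strategy.label,
        total_cost=float(cost.mean()),
        total_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        n_individuals=n,
    )
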