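"""Synthetic age-indexed probability schedules and parameter perturbation.

The cohort model needs eight age curves (CHD/stroke incidence for healthy
and untreated-hypertensive adults, hypertension incidence, background
treatment uptake, CVD and non-CVD mortality) that in practice come from
national life tables and burden-of-disease extracts. This module generates
plausible, seedable stand-ins so the whole pipeline runs self-contained:
Gompertz (log-linear in age) curves for mortality, logistic (logit-linear)
curves for incidence, with untreated-hypertensive event risk constructed as
a fixed multiple of the general-population risk so the relative ordering of
risks is guaranteed at every age. The curves are calibrated qualitatively
(lifetime CVD-event risk from age 30 around 0.45-0.50) and make no claim
of matching any country's surveillance data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .parameters import (
    SCHEDULE_NAMES,
    AgeSchedule,
    ModelParameters,
    _resolve,
    sync_derived,
)

AGE_MIN = 30
AGE_MAX = 100

SHAPES = ("gompertz", "logistic", "constant")


@dataclass(frozen=True)
class ScheduleSpec:
    """Recipe for one synthetic age curve.

    ``level_at_30`` and ``level_at_70`` anchor the curve exactly at those
    ages; the shape interpolates (and extrapolates to ``AGE_MAX``) between
    them.
    """

    name: str
    shape: str
    level_at_30: float
    level_at_70: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown schedule shape {self.shape!r}")
        for lvl in (self.level_at_30, self.level_at_70):
            if not (0.0 <= lvl <= 1.0):
                raise ValueError(f"{self.name}: anchor level {lvl} outside [0, 1]")
        if self.shape in ("gompertz", "logistic"):
            if self.level_at_70 < self.level_at_30:
                raise ValueError(
                    f"{self.name}: monotone shape needs level_at_70 >= level_at_30"
                )
            if self.level_at_30 <= 0.0 or self.level_at_70 >= 1.0:
                raise ValueError(
                    f"{self.name}: gompertz/logistic anchors must lie in (0, 1)"
                )


def generate_schedule(spec: ScheduleSpec) -> AgeSchedule:
    """Deterministic closed-form curve through the spec's two anchors."""
    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    if spec.shape == "constant":
        values = np.full_like(ages, spec.level_at_30)
    elif spec.shape == "gompertz":
        # exponential hazard growth: log v linear in age
        b = np.log(spec.level_at_70 / spec.level_at_30) / 40.0
        values = np.clip(spec.level_at_30 * np.exp(b * (ages - AGE_MIN)), 0.0, 1.0)
    else:  # logistic
        logit = lambda p: np.log(p / (1.0 - p))
        l30, l70 = logit(spec.level_at_30), logit(spec.level_at_70)
        x = l30 + (l70 - l30) / 40.0 * (ages - AGE_MIN)
        values = 1.0 / (1.0 + np.exp(-x))
    return AgeSchedule(name=spec.name, age_min=AGE_MIN, age_max=AGE_MAX, values=values)


# base anchor levels before seed jitter: (shape, level_at_30, level_at_70).
# Event-incidence anchors are pinned to the published screen-cycle risk
# constants (general-population CHD/stroke event probabilities near
# 0.010/0.003 per year over the screened ages, untreated-hypertensive risks
# near 0.014/0.006), so the age curves and the screening-cycle risk rows
# describe the same underlying epidemiology.
_BASE_ANCHORS = {
    "healthy_chd": ("logistic", 0.008, 0.013),
    "healthy_stroke": ("logistic", 0.002, 0.0042),
    "htn_incidence": ("logistic", 0.005, 0.030),
    "treatment_uptake": ("logistic", 0.10, 0.18),
    "cvd_death": ("gompertz", 0.0003, 0.006),
    "noncvd_death": ("gompertz", 0.002, 0.025),
}

#: excess event risk of untreated hypertension over the general population,
#: matching the ratio of the untreated to general screen-cycle constants
_HTN_RISK_MULTIPLIER = {"chd": 1.4, "stroke": 2.0}


def default_schedule_set(seed: int) -> dict[str, AgeSchedule]:
    """All eight schedules required by :class:`ModelParameters`.

    The seed jitters the anchor levels (+-10%) so distinct seeds give
    distinct but equally plausible curve sets. Untreated-hypertensive
    CHD/stroke schedules are the corresponding general-population curve
    times a risk multiplier > 1, so untreated risk exceeds healthy risk at
    every age by construction.
    """
    rng = np.random.default_rng(seed)
    schedules: dict[str, AgeSchedule] = {}
    for name, (shape, v30, v70) in _BASE_ANCHORS.items():
        j30, j70 = rng.uniform(0.9, 1.1, size=2)
        lo = v30 * j30
        hi = max(v70 * j70, lo)  # keep monotone anchors under jitter
        spec = ScheduleSpec(name=name, shape=shape, level_at_30=lo, level_at_70=hi, seed=seed)
        schedules[name] = generate_schedule(spec)
    for event in ("chd", "stroke"):
        mult = _HTN_RISK_MULTIPLIER[event] * rng.uniform(0.95, 1.05)
        base = schedules[f"healthy_{event}"]
        schedules[f"untreated_{event}"] = AgeSchedule(
            name=f"untreated_{event}",
            age_min=base.age_min,
            age_max=base.age_max,
            values=np.clip(base.values * mult, 0.0, 1.0),
        )
    return {name: schedules[name] for name in SCHEDULE_NAMES}


def perturb_parameters(
    params: ModelParameters, scale: float, seed: int
) -> ModelParameters:
    """Multiply every non-fixed scalar by a random factor in [1-scale, 1+scale].

    Results are clipped to each parameter's domain; fixed parameters (no CI)
    and the age schedules are left untouched. Deterministic given the seed.
    """
    if not (0.0 <= scale < 1.0):
        raise ValueError(f"scale must be in [0, 1), got {scale}")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(params)
    for path, pv in sorted(out.uncertainty.items()):
        if pv.fixed:
            continue
        factor = rng.uniform(1.0 - scale, 1.0 + scale)
        lo, hi = pv.domain()
        new = float(np.clip(pv.value * factor, lo, min(hi, np.finfo(float).max)))
        _resolve(out, path.split("."), set_to=new)
        out.uncertainty[path] = pv.__class__(
            name=pv.name, value=new, kind=pv.kind,
            ci_low=pv.ci_low, ci_high=pv.ci_high, source=pv.source,
        )
    return sync_derived(out)
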