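"""Screening strategies and the single-round screening operation.

A strategy is defined by a start age, a repeat interval in years and a stop
age (screening rounds at start, start+interval, ... up to the stop age).
One screening round partitions the healthy and the untreated-hypertensive
occupancy into participation and test-outcome sub-populations. The
screening test is imperfect (sensitivity/specificity below one); every
screen-positive receives a confirmatory diagnostic work-up assumed perfectly
accurate, so false positives are returned to the healthy state and only
true positives can begin treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ModelParameters


@dataclass(frozen=True)
class ScreeningStrategy:
    """``start_age is None`` (and then ``interval_years is None``) means no
    screening."""

    label: str
    start_age: int | None
    interval_years: int | None
    stop_age: int = 70

    def __post_init__(self) -> None:
        if (self.start_age is None) != (self.interval_years is None):
            raise ValueError(
                f"{self.label!r}: start_age and interval_years must both be "
                "set or both be None"
            )
        if self.start_age is not None:
            if self.interval_years < 1:
                raise ValueError(f"{self.label!r}: interval must be >= 1 year")
            if self.start_age > self.stop_age:
                raise ValueError(f"{self.label!r}: start_age > stop_age")

    @property
    def screens(self) -> bool:
        return self.start_age is not None

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "start_age": self.start_age,
            "interval_years": self.interval_years,
            "stop_age": self.stop_age,
        }


NO_SCREENING_LABEL = "No screening"


def is_screening_cycle(strategy: ScreeningStrategy, age: int) -> bool:
    """True when the attained age falls on one of the strategy's rounds."""
    if not strategy.screens:
        return False
    if age < strategy.start_age or age > strategy.stop_age:
        return False
    return (age - strategy.start_age) % strategy.interval_years == 0


@dataclass(frozen=True)
class ScreenOutcome:
    """Mass split of one screened state in one round, plus round costs."""

    true_positive: float = 0.0
    false_negative: float = 0.0
    false_positive: float = 0.0
    true_negative: float = 0.0
    not_participating: float = 0.0
    screening_cost: float = 0.0
    confirmatory_cost: float = 0.0

    @property
    def participants(self) -> float:
        return (
            self.true_positive
            + self.false_negative
            + self.false_positive
            + self.true_negative
        )

    @property
    def total_mass(self) -> float:
        return self.participants + self.not_participating


def apply_screening(
    healthy_mass: float, untreated_mass: float, params: ModelParameters
) -> tuple[ScreenOutcome, ScreenOutcome]:
    """Split healthy and untreated occupancy through one screening round.

    Healthy participants test negative with probability ``specificity``
    (true negatives) and positive otherwise (false positives); untreated
    hypertensives test positive with probability ``sensitivity`` (true
    positives) and negative otherwise (false negatives). Each participant
    incurs the screening contact cost; each screen-positive (true or false)
    incurs the confirmatory work-up cost. The confirmatory test reclassifies
    every false positive as healthy.
    """
    if healthy_mass < 0 or untreated_mass < 0:
        raise ValueError("state masses must be non-negative")
    scr = params.screening
    c = params.costs

    part_h = healthy_mass * scr.participation_healthy
    fp = part_h * (1.0 - scr.specificity)
    healthy_out = ScreenOutcome(
        true_negative=part_h * scr.specificity,
        false_positive=fp,
        not_participating=healthy_mass - part_h,
        screening_cost=part_h * c.screening_contact,
        confirmatory_cost=fp * c.confirmatory_workup,
    )

    part_u = untreated_mass * scr.participation_untreated
    tp = part_u * scr.sensitivity
    untreated_out = ScreenOutcome(
        true_positive=tp,
        false_negative=part_u * (1.0 - scr.sensitivity),
        not_participating=untreated_mass - part_u,
        screening_cost=part_u * c.screening_contact,
        confirmatory_cost=tp * c.confirmatory_workup,
    )
    return healthy_out, untreated_out


def strategy_roster() -> list[ScreeningStrategy]:
    """The ten evaluated strategies: no screening, then every combination of
    start age {30, 40, 50} and interval {1, 2, 3} years, all stopping at 70."""
    roster = [ScreeningStrategy(NO_SCREENING_LABEL, None, None)]
    interval_phrase = {1: "Annual screening", 2: "Screening every two years",
                       3: "Screening every three years"}
    for interval in (1, 2, 3):
        for start in (30, 40, 50):
            roster.append(
                ScreeningStrategy(
                    label=f"{interval_phrase[interval]} from the age of {start}",
                    start_age=start,
                    interval_years=interval,
                )
            )
    return roster


def strategy_by_label(label: str) -> ScreeningStrategy:
    for s in strategy_roster():
        if s.label == label:
            return s
    raise KeyError(f"unknown strategy label {label!r}")
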