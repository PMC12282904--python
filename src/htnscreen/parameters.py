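"""Model parameters: containers, loading, validation, serialization.

The decision model is driven by a single :class:`ModelParameters` object
holding every point estimate (screening test characteristics, treatment
effects, event decompositions, post-event risks, costs, utilities, the
initial state distribution and analysis settings) plus eight age-indexed
probability schedules. Scalar parameters live in a JSON document; each
schedule is a two-column ``age,value`` CSV. Parameters that carry a 95%
confidence interval are eligible for probabilistic sensitivity analysis;
those without are treated as fixed.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PARAMETER_KINDS = {"probability", "cost", "utility", "relative_risk", "rate"}

#: canonical names of the eight required age-indexed schedules
SCHEDULE_NAMES = (
    "healthy_chd",
    "healthy_stroke",
    "htn_incidence",
    "untreated_chd",
    "untreated_stroke",
    "treatment_uptake",
    "cvd_death",
    "noncvd_death",
)

CURRENCY_LABEL = "PPP_int$_2020"


class SchemaError(ValueError):
    """A required field is missing or malformed in a parameter file."""


class ValidationError(ValueError):
    """A parameter value violates its domain invariant."""


class DegenerateBranchError(ValueError):
    """A chance-node branch has zero total probability."""


@dataclass(frozen=True)
class ParameterValue:
    """A single named scalar with optional 95% CI.

    ``name`` is the dot-path of the value inside :class:`ModelParameters`
    (e.g. ``"utilities.post_stroke"``), which is also how one-way and
    probabilistic sensitivity analyses address it.
    """

    name: str
    value: float
    kind: str
    ci_low: float | None = None
    ci_high: float | None = None
    source: str = ""

    @property
    def fixed(self) -> bool:
        """True when no CI is available; fixed parameters are not sampled."""
        return self.ci_low is None or self.ci_high is None

    def domain(self) -> tuple[float, float]:
        if self.kind in ("probability", "utility"):
            return (0.0, 1.0)
        if self.kind == "relative_risk":
            return (np.nextafter(0.0, 1.0), math.inf)
        return (0.0, math.inf)  # cost, rate


def orient_ci(low: float, high: float) -> tuple[float, float]:
    """Return the interval endpoints in ascending order.

    Some printed intervals are typeset high-low; orienting never touches
    the point estimate.
    """
    return (low, high) if low <= high else (high, low)


def renormalize_branch(probs: list[float] | np.ndarray) -> list[float]:
    """Rescale non-negative branch probabilities to sum to exactly 1."""
    arr = np.asarray(probs, dtype=float)
    if (arr < 0).any():
        raise ValidationError(f"branch probabilities must be >= 0, got {probs}")
    total = arr.sum()
    if total <= 0:
        raise DegenerateBranchError("all-zero branch cannot be renormalized")
    return list(arr / total)


@dataclass
class AgeSchedule:
    """One probability per integer age on [age_min, age_max]."""

    name: str
    age_min: int
    age_max: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def at(self, age: int | float) -> float:
        a = int(age)
        if a < self.age_min or a > self.age_max:
            raise ValueError(
                f"schedule {self.name!r}: age {age} outside "
                f"[{self.age_min}, {self.age_max}]"
            )
        return float(self.values[a - self.age_min])

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.age_min, self.age_max + 1)

    def violations(self) -> list[str]:
        out = []
        n = self.age_max - self.age_min + 1
        if len(self.values) != n:
            out.append(
                f"schedule {self.name}: length {len(self.values)} != {n}"
            )
        if ((self.values < 0) | (self.values > 1)).any():
            out.append(f"schedule {self.name}: values outside [0, 1]")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "value": self.values})

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, name: str | None = None) -> "AgeSchedule":
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns) != ["age", "value"]:
            raise SchemaError(
                f"schedule file {path}: expected columns 'age,value', "
                f"got {list(df.columns)}"
            )
        ages = df["age"].to_numpy()
        if not (np.diff(ages) == 1).all():
            raise SchemaError(f"schedule file {path}: ages must be consecutive")
        return cls(
            name=name or Path(path).stem,
            age_min=int(ages[0]),
            age_max=int(ages[-1]),
            values=df["value"].to_numpy(dtype=float),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeSchedule):
            return NotImplemented
        return (
            self.name == other.name
            and self.age_min == other.age_min
            and self.age_max == other.age_max
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ScreeningParameters:
    participation_healthy: float = 0.563
    participation_untreated: float = 0.673
    sensitivity: float = 0.746
    specificity: float = 0.746
    confirm_sensitivity: float = 1.0
    confirm_specificity: float = 1.0
    uptake_true_positive: float = 0.9
    # printed complement of specificity, kept for a consistency check
    p_false_positive: float | None = 0.254


@dataclass
class TreatmentEffect:
    rr_chd_on_treatment: float = 0.675
    rr_stroke_on_treatment: float = 0.622
    rr_chd_recurrence: float = 2.4
    p_stroke_recurrence: float = 0.0485


@dataclass
class EventDecomposition:
    """Within-cycle split of a CHD or stroke event into its outcomes.

    Printed branch probabilities need not sum to one; the engine consumes
    the proportionally renormalized branches.
    """

    chd_fatal: float = 0.122
    chd_mi: float = 0.261
    chd_sa: float = 0.503
    chd_ua: float = 0.157
    stroke_fatal: float = 0.1435
    stroke_nonfatal: float = 0.518
    stroke_tia: float = 0.188

    def chd_branch(self, renormalize: bool = True) -> dict[str, float]:
        raw = {
            "fatal": self.chd_fatal,
            "mi": self.chd_mi,
            "sa": self.chd_sa,
            "ua": self.chd_ua,
        }
        if not renormalize:
            return raw
        vals = renormalize_branch(list(raw.values()))
        return dict(zip(raw, vals))

    def stroke_branch(self, renormalize: bool = True) -> dict[str, float]:
        raw = {
            "fatal": self.stroke_fatal,
            "nonfatal": self.stroke_nonfatal,
            "tia": self.stroke_tia,
        }
        if not renormalize:
            return raw
        vals = renormalize_branch(list(raw.values()))
        return dict(zip(raw, vals))


@dataclass
class PostEventRisks:
    cv_death_post_mi: float = 0.027
    cv_death_post_stroke: float = 0.027
    cv_death_post_sa: float = 0.020
    cv_death_post_ua: float = 0.022
    cv_death_post_tia: float = 0.014
    event_risk_false_positive_chd: float = 0.010
    event_risk_false_positive_stroke: float = 0.003
    event_risk_true_positive_chd: float = 0.014
    event_risk_true_positive_stroke: float = 0.006
    event_risk_false_negative_chd: float = 0.014
    event_risk_false_negative_stroke: float = 0.006


@dataclass
class CostSet:
    """All monetary inputs, in PPP international dollars (2020)."""

    screening_contact: float = 1.56
    confirmatory_workup: float = 212.57
    tx_new_no_screen: float = 137.85
    tx_new_with_screen: float = 139.41
    tx_previous: float = 57.56
    tx_average: float = 63.72
    event_year: dict[str, float] = field(
        default_factory=lambda: {
            "mi": 16018.61,
            "ua": 10484.27,
            "sa": 8111.67,
            "stroke": 45152.33,
            "tia": 9077.78,
        }
    )
    post_event_incremental: dict[str, float] = field(
        default_factory=lambda: {
            "post_mi": 471.33,
            "post_stroke": 8618.0,
            "post_sa": 121.68,
            "post_tia": 237.93,
            "post_ua": 282.80,
        }
    )
    death_year: dict[str, float] = field(
        default_factory=lambda: {"chd": 8872.59, "stroke": 32119.09}
    )


@dataclass
class UtilitySet:
    healthy: float = 1.0
    htn_off_tx: float = 0.946
    htn_on_tx: float = 1.0
    post_mi: float = 0.760
    post_stroke: float = 0.629
    post_sa: float = 0.808
    post_tia: float = 1.0
    post_ua: float = 0.770
    dead: float = 0.0


@dataclass
class InitialDistribution:
    """Cohort split at model entry; printed values sum to 0.999."""

    healthy: float = 0.921
    htn_on_tx: float = 0.041
    htn_off_tx: float = 0.037

    def as_tuple(self, renormalize: bool = True) -> tuple[float, float, float]:
        vals = (self.healthy, self.htn_off_tx, self.htn_on_tx)
        if not renormalize:
            return vals
        h, off, on = renormalize_branch(list(vals))
        return (h, off, on)


@dataclass
class AnalysisConfig:
    discount_rate_costs: float = 0.05
    discount_rate_outcomes: float = 0.05
    n_cycles: int = 70
    cohort_entry_age: int = 30
    wtp_threshold: float = 20652.44
    psa_iterations: int = 1000
    rng_seed: int = 0


@dataclass
class ModelParameters:
    """Single source of truth for one model run."""

    screening: ScreeningParameters = field(default_factory=ScreeningParameters)
    effects: TreatmentEffect = field(default_factory=TreatmentEffect)
    decomposition: EventDecomposition = field(default_factory=EventDecomposition)
    post_risks: PostEventRisks = field(default_factory=PostEventRisks)
    costs: CostSet = field(default_factory=CostSet)
    utilities: UtilitySet = field(default_factory=UtilitySet)
    initial: InitialDistribution = field(default_factory=InitialDistribution)
    schedules: dict[str, AgeSchedule] = field(default_factory=dict)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)
    #: proportional renormalization of event branches / initial distribution
    renormalize: bool = True
    #: dot-path -> ParameterValue metadata (CIs, kinds, sources)
    uncertainty: dict[str, ParameterValue] = field(default_factory=dict)

    def get_value(self, path: str) -> float:
        return float(_resolve(self, path.split("."), set_to=None))

    def with_value(self, path: str, value: float) -> "ModelParameters":
        """Return a copy with the parameter at ``path`` replaced."""
        out = copy.deepcopy(self)
        current = _resolve(self, path.split("."), set_to=None)
        cast = int if isinstance(current, int) and not isinstance(current, bool) else float
        _resolve(out, path.split("."), set_to=cast(value))
        if path in out.uncertainty:
            out.uncertainty[path] = dataclasses.replace(
                out.uncertainty[path], value=float(value)
            )
        return out

    def parameter_values(self) -> Iterator[ParameterValue]:
        yield from self.uncertainty.values()


def _resolve(obj, keys: list[str], set_to: float | None):
    """Walk attributes / dict keys along a dot path; get or set the leaf."""
    head = obj
    for k in keys[:-1]:
        head = head[k] if isinstance(head, dict) else getattr(head, k)
    last = keys[-1]
    if isinstance(head, dict):
        if last not in head:
            raise KeyError(f"unknown parameter path {'.'.join(keys)!r}")
        if set_to is None:
            return head[last]
        head[last] = set_to
    else:
        if not hasattr(head, last):
            raise KeyError(f"unknown parameter path {'.'.join(keys)!r}")
        if set_to is None:
            return getattr(head, last)
        setattr(head, last, set_to)
    return set_to


# ---------------------------------------------------------------------------
# kind inference

_SECTION_KINDS = {
    "screening": "probability",
    "decomposition": "probability",
    "post_risks": "probability",
    "initial": "probability",
    "costs": "cost",
    "utilities": "utility",
}
_EFFECT_KINDS = {
    "rr_chd_on_treatment": "relative_risk",
    "rr_stroke_on_treatment": "relative_risk",
    "rr_chd_recurrence": "relative_risk",
    "p_stroke_recurrence": "probability",
}


def _kind_for(section: str, name: str) -> str:
    if section == "effects":
        return _EFFECT_KINDS[name]
    return _SECTION_KINDS[section]


# ---------------------------------------------------------------------------
# loading

_SECTION_TYPES = {
    "screening": ScreeningParameters,
    "effects": TreatmentEffect,
    "decomposition": EventDecomposition,
    "post_risks": PostEventRisks,
    "costs": CostSet,
    "utilities": UtilitySet,
    "initial": InitialDistribution,
    "config": AnalysisConfig,
}


def _parse_leaf(section: str, path: str, raw, registry: dict) -> float:
    """Parse a scalar leaf that is either a number or {value, ci, source}."""
    if isinstance(raw, (int, float)):
        value, ci, source = float(raw), None, ""
    elif isinstance(raw, dict):
        if "value" not in raw:
            raise SchemaError(f"{path}: object leaf must carry 'value'")
        value = float(raw["value"])
        ci = raw.get("ci")
        source = raw.get("source", "")
        if ci is not None:
            if len(ci) != 2:
                raise SchemaError(f"{path}: 'ci' must be a [low, high] pair")
            lo, hi = orient_ci(float(ci[0]), float(ci[1]))
            if (lo, hi) != (float(ci[0]), float(ci[1])):
                log.info("reoriented reversed CI for %s", path)
            ci = (lo, hi)
    else:
        raise SchemaError(f"{path}: expected number or object, got {type(raw)}")
    name = path.split(".", 1)[1] if "." in path else path
    kind = _kind_for(section, path.split(".")[1]) if section != "config" else None
    if kind is not None:
        registry[path] = ParameterValue(
            name=path,
            value=value,
            kind=kind,
            ci_low=None if ci is None else ci[0],
            ci_high=None if ci is None else ci[1],
            source=source,
        )
    return value


def _build_section(section: str, data: dict, registry: dict):
    cls = _SECTION_TYPES[section]
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            if section == "config" or f.name == "p_false_positive":
                continue  # config fields and consistency checks are optional
            raise SchemaError(f"missing required field {section}.{f.name}")
        raw = data[f.name]
        if isinstance(raw, dict) and "value" not in raw:
            # nested map (cost sub-tables)
            sub = {}
            for k, v in raw.items():
                sub[k] = _parse_leaf(section, f"{section}.{f.name}.{k}", v, registry)
            kwargs[f.name] = sub
        elif section == "config":
            kwargs[f.name] = type(f.default)(raw) if f.default is not None else raw
        else:
            kwargs[f.name] = _parse_leaf(section, f"{section}.{f.name}", raw, registry)
    unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
    if unknown:
        raise SchemaError(f"unknown field(s) in {section}: {sorted(unknown)}")
    return cls(**kwargs)


def load_parameters(
    path: str | Path,
    schedule_path: str | Path | None = None,
    *,
    synthetic_seed: int | None = None,
    renormalize: bool = True,
    strict: bool = True,
) -> ModelParameters:
    """Load and validate a full parameter set.

    ``path`` is the scalar-parameter JSON document. Schedules come either
    from ``schedule_path`` (a directory of ``<name>.csv`` files) or, when
    ``synthetic_seed`` is given, from the synthetic schedule generator.
    With ``strict=False`` invariant violations are logged instead of
    raised, so e.g. raw unnormalized branches can be inspected.
    """
    with open(path) as fh:
        doc = json.load(fh)
    registry: dict[str, ParameterValue] = {}
    sections = {}
    for section in _SECTION_TYPES:
        if section not in doc:
            raise SchemaError(f"missing required section {section!r}")
        sections[section] = _build_section(section, doc[section], registry)

    if schedule_path is not None:
        sched_dir = Path(schedule_path)
        schedules = {}
        for name in SCHEDULE_NAMES:
            f = sched_dir / f"{name}.csv"
            if not f.exists():
                raise SchemaError(f"missing schedule file {f}")
            schedules[name] = AgeSchedule.from_csv(f, name=name)
    elif synthetic_seed is not None:
        from .synthetic import default_schedule_set

        schedules = default_schedule_set(synthetic_seed)
    else:
        raise SchemaError(
            "no schedules: pass schedule_path or synthetic_seed"
        )

    params = ModelParameters(
        screening=sections["screening"],
        effects=sections["effects"],
        decomposition=sections["decomposition"],
        post_risks=sections["post_risks"],
        costs=sections["costs"],
        utilities=sections["utilities"],
        initial=sections["initial"],
        schedules=schedules,
        config=sections["config"],
        renormalize=renormalize,
        uncertainty=registry,
    )
    problems = validate(params)
    if problems:
        if strict:
            raise ValidationError("; ".join(problems))
        for p in problems:
            log.warning("parameter violation: %s", p)
    return params


def validate(params: ModelParameters) -> list[str]:
    """Return every invariant violation (empty list = valid)."""
    out: list[str] = []
    for pv in params.parameter_values():
        lo, hi = pv.domain()
        if not (lo <= pv.value <= hi):
            out.append(
                f"{pv.name} = {pv.value} outside [{lo:g}, {hi:g}] "
                f"for kind {pv.kind}"
            )
        if not pv.fixed and not (pv.ci_low <= pv.value <= pv.ci_high):
            out.append(
                f"{pv.name}: point estimate {pv.value} outside oriented CI "
                f"({pv.ci_low}, {pv.ci_high})"
            )
    eff = params.effects
    if not (0 < eff.rr_chd_on_treatment <= 1):
        out.append(f"effects.rr_chd_on_treatment = {eff.rr_chd_on_treatment} not in (0, 1]")
    if not (0 < eff.rr_stroke_on_treatment <= 1):
        out.append(f"effects.rr_stroke_on_treatment = {eff.rr_stroke_on_treatment} not in (0, 1]")
    if eff.rr_chd_recurrence < 1:
        out.append(f"effects.rr_chd_recurrence = {eff.rr_chd_recurrence} < 1")

    scr = params.screening
    if scr.p_false_positive is not None:
        if abs((1.0 - scr.specificity) - scr.p_false_positive) > 1e-9:
            out.append(
                "screening: 1 - specificity "
                f"({1.0 - scr.specificity:.6g}) != printed false-positive "
                f"probability {scr.p_false_positive}"
            )

    if not params.renormalize:
        d = params.decomposition
        s_chd = d.chd_fatal + d.chd_mi + d.chd_sa + d.chd_ua
        if abs(s_chd - 1.0) > 1e-9:
            out.append(f"CHD decomposition sums to {s_chd:.4g}")
        s_str = d.stroke_fatal + d.stroke_nonfatal + d.stroke_tia
        if abs(s_str - 1.0) > 1e-9:
            out.append(f"stroke decomposition sums to {s_str:.4g}")
        ini = params.initial
        s_ini = ini.healthy + ini.htn_off_tx + ini.htn_on_tx
        if abs(s_ini - 1.0) > 1e-9:
            out.append(f"initial distribution sums to {s_ini:.4g}")

    cfg = params.config
    if not (0 <= cfg.discount_rate_costs < 1):
        out.append(f"config.discount_rate_costs = {cfg.discount_rate_costs} not in [0, 1)")
    if not (0 <= cfg.discount_rate_outcomes < 1):
        out.append(f"config.discount_rate_outcomes = {cfg.discount_rate_outcomes} not in [0, 1)")
    if cfg.n_cycles < 1:
        out.append(f"config.n_cycles = {cfg.n_cycles} < 1")
    if cfg.wtp_threshold < 0:
        out.append(f"config.wtp_threshold = {cfg.wtp_threshold} < 0")

    for name in SCHEDULE_NAMES:
        if name not in params.schedules:
            out.append(f"missing schedule {name!r}")
        else:
            out.extend(params.schedules[name].violations())
    return out


def sync_derived(params: ModelParameters) -> ModelParameters:
    """Refresh consistency fields after a parameter change (in place).

    The printed false-positive probability is the complement of
    specificity; whenever specificity is varied (perturbation, sensitivity
    analysis) the stored complement must follow.
    """
    if params.screening.p_false_positive is not None:
        params.screening.p_false_positive = 1.0 - params.screening.specificity
    return params


# ---------------------------------------------------------------------------
# serialization

def to_dict(params: ModelParameters) -> dict:
    """Nested JSON-serializable form (scalars only; schedules go to CSV)."""
    doc: dict = {"currency": CURRENCY_LABEL}
    for section, cls in _SECTION_TYPES.items():
        obj = getattr(params, section)
        sec: dict = {}
        for f in dataclasses.fields(cls):
            val = getattr(obj, f.name)
            if val is None:
                continue
            if isinstance(val, dict):
                sub = {}
                for k, v in val.items():
                    sub[k] = _leaf_out(params, f"{section}.{f.name}.{k}", v)
                sec[f.name] = sub
            elif section == "config":
                sec[f.name] = val
            else:
                sec[f.name] = _leaf_out(params, f"{section}.{f.name}", val)
        doc[section] = sec
    return doc


def _leaf_out(params: ModelParameters, path: str, value: float):
    pv = params.uncertainty.get(path)
    if pv is None or pv.fixed:
        if pv is not None and pv.source:
            return {"value": value, "source": pv.source}
        return value
    out = {"value": value, "ci": [pv.ci_low, pv.ci_high]}
    if pv.source:
        out["source"] = pv.source
    return out


def save_parameters(
    params: ModelParameters,
    path: str | Path,
    schedule_dir: str | Path | None = None,
) -> None:
    with open(path, "w") as fh:
        json.dump(to_dict(params), fh, indent=1, sort_keys=True)
        fh.write("\n")
    if schedule_dir is not None:
        sched_dir = Path(schedule_dir)
        sched_dir.mkdir(parents=True, exist_ok=True)
        for name, sched in params.schedules.items():
            sched.to_csv(sched_dir / f"{name}.csv")


def parameters_equal(a: ModelParameters, b: ModelParameters) -> bool:
    """Field-by-field equality, including schedules and CI metadata."""
    if to_dict(a) != to_dict(b):
        return False
    return a.schedules == b.schedules


# ---------------------------------------------------------------------------
# packaged base case

def base_case_path() -> Path:
    """Path of the packaged base-case scalar fixture."""
    return Path(resources.files("htnscreen").joinpath("data/base_case.json"))


def base_case(
    schedule_seed: int = 0, schedule_path: str | Path | None = None
) -> ModelParameters:
    """The base-case parameter set, with synthetic schedules by default."""
    if schedule_path is not None:
        return load_parameters(base_case_path(), schedule_path)
    return load_parameters(base_case_path(), synthetic_seed=schedule_seed)
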