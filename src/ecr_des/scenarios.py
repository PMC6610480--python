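"""Named, pure transformations of the baseline service model.

Each transform takes an :class:`~ecr_des.model.ECRModel` and returns an
edited copy (the input is never mutated), so scenarios compose left to
right and the baseline is a fixed point of the identity scenario.

Shipped scenarios
-----------------
- ``baseline`` — the service as parameterized (identity).
- ``exclusive`` — the biplane suite (angioINR) is closed to elective IR
  patients; stroke, elective INR and emergency IR retain access.
- ``two-inr`` — the single-plane angioIR suite is replaced by a second
  angioINR; every angiography class routes to either suite by shortest
  queue; staffing is unchanged.
- ``extended:H`` (H in {1, 2}) — the day shift of every staffed (human)
  resource ends H hours later, and the elective service-start window
  extends identically.  Physical machines have no shift to extend.
- ``demand:K`` — patient demand scaled by K (mode per the model's
  ``demand_mode``, default the stroke funnel only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .engine import CapacitySchedule, MINUTES_PER_DAY, ResourceSpec
from .errors import ConfigValidationError
from .model import ANGIO_CLASSES, ECRModel

__all__ = [
    "Scenario",
    "apply_exclusive_use",
    "apply_two_angioinr",
    "apply_extended_schedule",
    "apply_demand_multiplier",
    "parse_scenario",
    "apply_scenario",
]


def apply_exclusive_use(model: ECRModel) -> ECRModel:
    """Restrict the angioINR to stroke, elective INR and emergency IR patients."""
    out = []
    for r in model.resources:
        if r.name == "angio_inr" and "elective_ir" in r.eligible_classes:
            r = r.replace(eligible_classes=r.eligible_classes - {"elective_ir"})
        out.append(r)
    return model.with_resources(out)


def apply_two_angioinr(model: ECRModel) -> ECRModel:
    """Replace the angioIR with a second angioINR; all classes route to either.

    Staffing (physician and staff pools) is unchanged; only the suites are
    edited, doubling biplane availability for ECR patients.
    """
    out = []
    for r in model.resources:
        if r.name == "angio_ir":
            continue
        if r.name == "angio_inr":
            r = r.replace(eligible_classes=frozenset(ANGIO_CLASSES))
            out.append(r)
            out.append(
                ResourceSpec(
                    "angio_inr_2",
                    r.schedule,
                    frozenset(ANGIO_CLASSES),
                    kind="suite",
                    human=False,
                )
            )
            continue
        out.append(r)
    return model.with_resources(out)


def _extend_schedule(schedule: CapacitySchedule, day_end: float, new_end: float) -> CapacitySchedule:
    """Move the boundary at ``day_end`` to ``new_end`` within the following segment."""
    segs = list(schedule.segments)
    out = []
    for i, (s, e, c) in enumerate(segs):
        if e == day_end and i + 1 < len(segs):
            nxt_s, nxt_e, nxt_c = segs[i + 1]
            if new_end >= nxt_e:
                raise ConfigValidationError(
                    [f"extended day end {new_end} swallows the night segment ({nxt_s}, {nxt_e})"]
                )
            out.append((s, new_end, c))
            segs[i + 1] = (new_end, nxt_e, nxt_c)
        else:
            out.append((s, e, c))
    return CapacitySchedule(tuple(out))


def apply_extended_schedule(model: ECRModel, extra_hours: int) -> ECRModel:
    """Extend the day shift of all human resources (and the elective gate) by 1 or 2 h."""
    if extra_hours not in (1, 2):
        raise ConfigValidationError(
            [f"scenario.extended: extra_hours must be 1 or 2, got {extra_hours}"]
        )
    day_end = float(model.params.gate[1])
    new_end = day_end + 60.0 * extra_hours
    if new_end > MINUTES_PER_DAY:
        raise ConfigValidationError(["scenario.extended: day end past midnight"])
    out = []
    for r in model.resources:
        if r.human and any(e == day_end for _, e, _ in r.schedule.segments[:-1]):
            r = r.replace(schedule=_extend_schedule(r.schedule, day_end, new_end))
        out.append(r)
    edited = model.with_resources(out)
    return edited.with_params(gate=(model.params.gate[0], new_end))


def apply_demand_multiplier(model: ECRModel, k: float) -> ECRModel:
    """Scale patient demand by ``k`` (mode set by ``ModelParams.demand_mode``)."""
    if k <= 0:
        raise ConfigValidationError([f"scenario.demand: multiplier must be > 0, got {k}"])
    return model.with_params(demand_multiplier=model.params.demand_multiplier * k)


_TRANSFORMS = {
    "baseline": lambda m: m,
    "exclusive": apply_exclusive_use,
    "exclusive_use": apply_exclusive_use,
    "two-inr": apply_two_angioinr,
    "two_angioinr": apply_two_angioinr,
}


@dataclass(frozen=True)
class Scenario:
    """A named, ordered composition of scenario transforms."""

    name: str = "baseline"
    steps: tuple = field(default=())  # tuple of (kind, arg)

    def apply(self, model: ECRModel) -> ECRModel:
        for kind, arg in self.steps:
            if kind == "extended":
                model = apply_extended_schedule(model, arg)
            elif kind == "demand":
                model = apply_demand_multiplier(model, arg)
            else:
                model = _TRANSFORMS[kind](model)
        return model


def parse_scenario(spec: str) -> Scenario:
    """Parse a CLI scenario spec, e.g. ``"exclusive,extended:1"`` or ``"demand:2"``."""
    spec = (spec or "baseline").strip()
    steps = []
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        m = re.fullmatch(r"extended:(\d+)", part)
        if m:
            steps.append(("extended", int(m.group(1))))
            continue
        m = re.fullmatch(r"demand:([0-9.]+)", part)
        if m:
            steps.append(("demand", float(m.group(1))))
            continue
        if part in _TRANSFORMS:
            steps.append((part, None))
            continue
        raise ConfigValidationError([f"scenario: unknown component '{part}'"])
    return Scenario(name=spec, steps=tuple(steps))


def apply_scenario(model: ECRModel, spec: str) -> ECRModel:
    return parse_scenario(spec).apply(model)
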