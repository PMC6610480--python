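"""The ECR service model: resources, arrival streams, pathways and priorities.

The model describes a comprehensive stroke service in which four patient
pathways compete for shared angiography resources:

1. **Stroke pathway** — a patient presents to the emergency department (ED),
   is triaged, assessed by the stroke team, scanned (CT), assessed for ECR
   (endovascular clot retrieval) eligibility, and finally undergoes ECR,
   which requires the biplane angiography suite (angioINR), an
   interventional neuroradiologist (INR) and angiography staff concurrently.
2. **Elective INR pathway** — elective neurointerventional cases using the
   angioINR suite with the INR.
3. **Emergency IR pathway** — emergency body-interventional cases that may
   use either suite (angioINR or the single-plane angioIR), with an
   interventional radiologist (IR).
4. **Elective IR pathway** — elective body-interventional cases, likewise
   routed to either suite by shortest queue.

Patients are generated by Poisson processes whose rates derive from annual
case counts; the stroke funnel (suspected stroke -> AIS -> ECR) is driven by
branch probabilities equal to ratios of those counts, so the downstream
rates are emergent expectations rather than independent streams.  Emergency
patients (stroke first, then emergency IR) jump queues ahead of electives
but never preempt a procedure in progress; elective procedures may only
start during work hours (08:00-17:00).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Optional

import numpy as np

from .engine import (
    CapacitySchedule,
    ModelDefinition,
    ResourceSpec,
    RngBank,
    StreamDef,
    run as engine_run,
)
from .errors import ConfigurationError, ConfigValidationError

MINUTES_PER_YEAR = 525_600.0

PATIENT_CLASSES = ("stroke", "elective_inr", "emergency_ir", "elective_ir", "ed_other")

ANGIO_CLASSES = ("stroke", "elective_inr", "emergency_ir", "elective_ir")

#: lower value = served first; emergencies ahead of electives, stroke first
DEFAULT_PRIORITIES = {
    "stroke": 0,
    "emergency_ir": 1,
    "elective_inr": 2,
    "elective_ir": 2,
    "ed_other": 2,
}

#: annual case counts logged over one year (the model's arrival-rate inputs)
DEFAULT_ANNUAL_COUNTS = {
    "ed": 107_700,
    "suspected_stroke": 750,
    "ais": 450,
    "ecr": 58,
    "elective_inr": 104,
    "emergency_ir": 468,
    "elective_ir": 3_805,
}

#: which physician pool each patient class's procedure requires
PHYSICIAN_FOR_CLASS = {
    "stroke": "inr",
    "elective_inr": "inr",
    "emergency_ir": "ir",
    "elective_ir": "ir",
}

PROCEDURE_DURATION_KEY = {
    "stroke": "ecr_procedure",
    "elective_inr": "elective_inr_procedure",
    "emergency_ir": "emergency_ir_procedure",
    "elective_ir": "elective_ir_procedure",
}

DAY_START = 480.0   # 08:00
DAY_END = 1020.0    # 17:00


@dataclass(frozen=True)
class DurationSpec:
    """Service-step duration distribution (minutes).

    ``cv`` (coefficient of variation) only matters for the lognormal family;
    fixed and exponential ignore it.
    """

    distribution: str = "lognormal"
    mean: float = 1.0
    cv: float = 0.5

    def __post_init__(self) -> None:
        if self.distribution not in ("fixed", "exponential", "lognormal"):
            raise ConfigurationError(f"unknown duration distribution '{self.distribution}'")
        if self.mean <= 0:
            raise ConfigurationError(f"duration mean must be > 0, got {self.mean}")
        if self.cv < 0:
            raise ConfigurationError(f"duration cv must be >= 0, got {self.cv}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.distribution == "fixed" or (self.distribution == "lognormal" and self.cv == 0):
            return np.full(size, self.mean)
        if self.distribution == "exponential":
            return rng.exponential(self.mean, size=size)
        sigma2 = math.log(1.0 + self.cv**2)
        mu = math.log(self.mean) - sigma2 / 2.0
        return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=size)


# Service durations are a calibration input, not logged data: means chosen so
# baseline angioINR occupancy lands in the mid-20s percent from annual
# busy-minute bookkeeping.  All configurable.
DEFAULT_DURATIONS = {
    "ed_triage": DurationSpec("lognormal", 15.0, 0.5),
    "stroke_assessment": DurationSpec("lognormal", 20.0, 0.5),
    "ct_scan": DurationSpec("lognormal", 20.0, 0.5),
    "angio_prep": DurationSpec("lognormal", 30.0, 0.5),
    "ecr_procedure": DurationSpec("lognormal", 120.0, 0.5),
    "elective_inr_procedure": DurationSpec("lognormal", 120.0, 0.5),
    "emergency_ir_procedure": DurationSpec("lognormal", 60.0, 0.5),
    "elective_ir_procedure": DurationSpec("lognormal", 60.0, 0.5),
}


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def derive_interarrival(annual_count: float, minutes_per_year: float = MINUTES_PER_YEAR) -> float:
    """Mean interarrival time in minutes from an annual case count (exact real)."""
    if annual_count is None or annual_count <= 0:
        raise ConfigValidationError([f"annual count must be positive, got {annual_count}"])
    return minutes_per_year / annual_count


def interarrival_report(annual_count: float) -> int:
    """Reporting view: interarrival minutes rounded to the nearest integer."""
    return int(round(derive_interarrival(annual_count)))


def derive_branch_probs(annual_counts: dict) -> dict:
    """Stroke-funnel branch probabilities from annual counts.

    Requires the nested funnel ED >= suspected stroke >= AIS >= ECR; the
    probabilities are ratios of consecutive counts so the downstream annual
    rates are reproduced in expectation.
    """
    ed = annual_counts["ed"]
    susp = annual_counts["suspected_stroke"]
    ais = annual_counts["ais"]
    ecr = annual_counts["ecr"]
    if not (ed >= susp >= ais >= ecr >= 0) or ed <= 0:
        raise ConfigValidationError(
            [f"annual counts must form a nested funnel ED >= suspected >= AIS >= ECR, "
             f"got {ed} >= {susp} >= {ais} >= {ecr}"]
        )
    return {
        "suspected": susp / ed,
        "ais": ais / susp if susp else 0.0,
        "ecr": ecr / ais if ais else 0.0,
    }


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """All rates, counts, probabilities and duration distributions.

    ``demand_multiplier`` scales patient demand according to ``demand_mode``:

    - ``"funnel"`` (default): scales the stroke funnel — P(suspected stroke |
      ED presentation) is multiplied, so suspected/AIS/ECR rates all scale
      while the raw ED volume and the elective/emergency IR streams stay at
      their logged rates.  This models growth in ECR demand specifically.
    - ``"ecr"``: scales only P(ECR | AIS).
    - ``"all"``: scales every arrival stream's rate.
    """

    annual_counts: dict = field(default_factory=lambda: dict(DEFAULT_ANNUAL_COUNTS))
    interarrival_overrides: dict = field(default_factory=dict)
    branch_overrides: dict = field(default_factory=dict)
    durations: dict = field(default_factory=lambda: dict(DEFAULT_DURATIONS))
    demand_multiplier: float = 1.0
    demand_mode: str = "funnel"
    background_ed: bool = True
    independent_streams: bool = False
    gate: tuple = (DAY_START, DAY_END)
    priorities: dict = field(default_factory=lambda: dict(DEFAULT_PRIORITIES))

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ConfigValidationError(problems)

    def validate(self) -> list[str]:
        problems = []
        if self.demand_multiplier <= 0:
            problems.append(f"demand.multiplier: must be > 0, got {self.demand_multiplier}")
        if self.demand_mode not in ("funnel", "ecr", "all"):
            problems.append(f"demand.mode: unknown mode '{self.demand_mode}'")
        for key, p in self.branch_overrides.items():
            if key not in ("suspected", "ais", "ecr"):
                problems.append(f"branching.{key}: unknown branch point")
            elif not (0.0 <= p <= 1.0):
                problems.append(f"branching.{key}: probability {p} outside [0, 1]")
        for key, n in self.annual_counts.items():
            if n < 0:
                problems.append(f"patients.annual_counts.{key}: negative count {n}")
        for key, ia in self.interarrival_overrides.items():
            if ia is not None and ia < 0:
                problems.append(f"patients.interarrival_min.{key}: negative value {ia}")
        if not problems:
            try:
                probs = self.branch_probs()
            except ConfigValidationError as exc:
                problems.extend(exc.problems)
            else:
                for key, p in probs.items():
                    if p > 1.0:
                        problems.append(
                            f"branching.{key}: effective probability {p:.4f} exceeds 1 "
                            f"(demand multiplier too large for this mode)"
                        )
        if not (0 <= self.gate[0] < self.gate[1] <= 1440.0):
            problems.append(f"gate: window {self.gate} must satisfy 0 <= start < end <= 1440")
        return problems

    # -- rates --------------------------------------------------------------

    def interarrival(self, stream: str) -> Optional[float]:
        """Effective mean interarrival minutes for a stream (demand-scaled)."""
        if stream in self.interarrival_overrides:
            base = self.interarrival_overrides[stream]
        else:
            count = self.annual_counts.get(stream, 0)
            if count <= 0:
                return None
            base = derive_interarrival(count)
        if base is None or base <= 0:
            return None
        k = self.demand_multiplier
        if self.demand_mode == "all" and k != 1.0:
            base = base / k
        elif self.demand_mode == "funnel" and stream == "suspected_stroke" and k != 1.0:
            # only used when the funnel is fed by a direct suspected-stroke stream
            base = base / k
        return base

    def branch_probs(self) -> dict:
        probs = derive_branch_probs(self.annual_counts)
        probs.update(self.branch_overrides)
        k = self.demand_multiplier
        if k != 1.0:
            if self.demand_mode == "funnel":
                probs["suspected"] = probs["suspected"] * k
            elif self.demand_mode == "ecr":
                probs["ecr"] = probs["ecr"] * k
        return probs

    def expected_ecr_per_year(self) -> float:
        probs = self.branch_probs()
        if self.independent_streams or not self.background_ed:
            ia = self.interarrival("suspected_stroke")
            susp = MINUTES_PER_YEAR / ia if ia else 0.0
            return susp * probs["ais"] * probs["ecr"]
        ia = self.interarrival("ed")
        ed = MINUTES_PER_YEAR / ia if ia else 0.0
        return ed * probs["suspected"] * probs["ais"] * probs["ecr"]


# ---------------------------------------------------------------------------
# resources
# ---------------------------------------------------------------------------

def default_resources() -> list[ResourceSpec]:
    """The service's resource pools, in fixed declaration (tie-break) order."""
    const = CapacitySchedule.constant
    day_night = CapacitySchedule.day_night
    return [
        ResourceSpec("angio_inr", const(1), frozenset(ANGIO_CLASSES), kind="suite"),
        ResourceSpec("angio_ir", const(1), frozenset({"emergency_ir", "elective_ir"}), kind="suite"),
        ResourceSpec("ct", const(2), frozenset({"stroke"}), kind="other"),
        ResourceSpec("inr", const(1), frozenset({"stroke", "elective_inr"}),
                     kind="physician", human=True),
        ResourceSpec("ir", day_night(2, 1), frozenset({"emergency_ir", "elective_ir"}),
                     kind="physician", human=True),
        ResourceSpec("angio_staff", day_night(6, 3), frozenset(ANGIO_CLASSES),
                     kind="staff", human=True),
        ResourceSpec("ed_team", const(10), frozenset({"ed_other", "stroke"}),
                     kind="other", human=True),
        ResourceSpec("stroke_team", const(1), frozenset({"stroke"}), kind="other", human=True),
    ]


# ---------------------------------------------------------------------------
# pathway steps
# ---------------------------------------------------------------------------

SUITE = "@suite"  # placeholder resolved by the routing step at run time


@dataclass(frozen=True)
class Step:
    """One step of a patient pathway (declarative; executed by the interpreter)."""

    kind: str                     # seize | timeout | release | branch | set_class | route | exit
    resources: tuple = ()         # ((name, units), ...) for seize/release
    duration: str = ""            # duration key for timeout
    prob: str = ""                # branch-probability key for branch
    new_class: str = ""           # for set_class
    candidates: tuple = ()        # suite names for route
    gated: bool = False           # seize may only start inside the work-hours gate


def _seize(*res, gated=False):
    return Step("seize", resources=tuple(res), gated=gated)


def _timeout(key):
    return Step("timeout", duration=key)


def _release(*res):
    return Step("release", resources=tuple(res))


def suites_for(resources: list[ResourceSpec], patient_class: str) -> tuple[str, ...]:
    return tuple(
        r.name for r in resources if r.kind == "suite" and patient_class in r.eligible_classes
    )


def build_stroke_pathway(
    params: ModelParams,
    resources: list[ResourceSpec],
    *,
    from_suspected: bool = False,
) -> tuple[Step, ...]:
    """ED triage -> stroke-team assessment -> CT -> eligibility -> ECR bundle.

    With ``from_suspected`` the arrival is already a suspected stroke (the
    P(suspected | ED) branch is skipped), used when the raw ED background
    stream is modelled separately or disabled.
    """
    needed = {"ed_team", "stroke_team", "ct", "inr", "angio_staff"}
    names = {r.name for r in resources}
    missing = sorted(needed - names)
    if missing:
        raise ConfigurationError(f"stroke pathway requires missing resources: {missing}")
    stroke_suites = suites_for(resources, "stroke")
    if not stroke_suites:
        raise ConfigurationError("stroke pathway requires at least one eligible suite")
    steps = [
        _seize(("ed_team", 1)),
        _timeout("ed_triage"),
        _release(("ed_team", 1)),
    ]
    if not from_suspected:
        steps.append(Step("branch", prob="suspected"))
    steps += [
        Step("set_class", new_class="stroke"),
        _seize(("stroke_team", 1)),
        _timeout("stroke_assessment"),
        _release(("stroke_team", 1)),
        _seize(("ct", 1)),
        _timeout("ct_scan"),
        _release(("ct", 1)),
        Step("branch", prob="ais"),
        Step("branch", prob="ecr"),
        Step("route", candidates=stroke_suites),
        _seize((SUITE, 1), ("inr", 1), ("angio_staff", 1)),
        _timeout("ecr_procedure"),
        _release((SUITE, 1), ("inr", 1), ("angio_staff", 1)),
        Step("exit"),
    ]
    return tuple(steps)


def build_background_ed_pathway() -> tuple[Step, ...]:
    """Non-stroke ED presentations: triage contention on the ED team only."""
    return (
        _seize(("ed_team", 1)),
        _timeout("ed_triage"),
        _release(("ed_team", 1)),
        Step("exit"),
    )


def build_angio_pathway(patient_class: str, resources: list[ResourceSpec]) -> tuple[Step, ...]:
    """Prep by angiography staff, then the procedure bundle on the shortest-queue suite."""
    if patient_class not in PHYSICIAN_FOR_CLASS:
        raise ConfigurationError(f"unknown angiography patient class '{patient_class}'")
    candidates = suites_for(resources, patient_class)
    if not candidates:
        raise ConfigurationError(f"class '{patient_class}' has no eligible angiography suite")
    physician = PHYSICIAN_FOR_CLASS[patient_class]
    names = {r.name for r in resources}
    for req in (physician, "angio_staff"):
        if req not in names:
            raise ConfigurationError(f"angio pathway requires missing resource '{req}'")
    elective = patient_class in ("elective_inr", "elective_ir")
    return (
        _seize(("angio_staff", 1)),
        _timeout("angio_prep"),
        _release(("angio_staff", 1)),
        Step("route", candidates=candidates),
        _seize((SUITE, 1), (physician, 1), ("angio_staff", 1), gated=elective),
        _timeout(PROCEDURE_DURATION_KEY[patient_class]),
        _release((SUITE, 1), (physician, 1), ("angio_staff", 1)),
        Step("exit"),
    )


# ---------------------------------------------------------------------------
# pathway interpreter and sampling context
# ---------------------------------------------------------------------------

_CHUNK = 2048


class SamplerBank:
    """Buffered named samplers for durations and branch draws.

    Every sampler owns an independent stream derived from the replication's
    root seed, so the same seed reproduces the same draws and scenarios
    sharing a seed share arrival and duration randomness (common random
    numbers).
    """

    def __init__(self, bank: RngBank, durations: dict, branch_probs: dict):
        self._bank = bank
        self._durations = durations
        self.branch_probs = branch_probs
        self._buf: dict[str, np.ndarray] = {}
        self._pos: dict[str, int] = {}

    def _next(self, key: str, refill) -> float:
        pos = self._pos.get(key, 0)
        buf = self._buf.get(key)
        if buf is None or pos >= len(buf):
            buf = refill()
            self._buf[key] = buf
            pos = 0
        self._pos[key] = pos + 1
        return float(buf[pos])

    def duration(self, key: str) -> float:
        spec = self._durations.get(key)
        if spec is None:
            raise ConfigurationError(f"no duration configured for step '{key}'")
        return self._next(
            "dur:" + key,
            lambda: spec.sample(self._bank.rng("dur:" + key), _CHUNK),
        )

    def uniform(self, key: str) -> float:
        return self._next(
            "branch:" + key,
            lambda: self._bank.rng("branch:" + key).random(_CHUNK),
        )


@lru_cache(maxsize=128)
def _compile_steps(steps: tuple) -> tuple:
    """Lower Step objects to plain op-tuples; static needs-dicts are shared.

    The engine only reads a seize/release needs mapping, so steps without
    the run-time suite placeholder reuse one dict across all patients.
    """
    ops = []
    for st in steps:
        kind = st.kind
        if kind in ("seize", "release"):
            dynamic = any(name == SUITE for name, _ in st.resources)
            static = None if dynamic else {name: units for name, units in st.resources}
            ops.append((kind, tuple(st.resources), static, st.gated))
        elif kind == "timeout":
            ops.append(("timeout", st.duration))
        elif kind == "branch":
            ops.append(("branch", st.prob))
        elif kind == "set_class":
            ops.append(("set_class", st.new_class))
        elif kind == "route":
            ops.append(("route", st.candidates))
        elif kind == "exit":
            ops.append(("exit",))
        else:  # pragma: no cover - steps are built in-package
            raise ConfigurationError(f"unknown pathway step kind '{st.kind}'")
    return tuple(ops)


def execute_pathway(entity, steps, ctx: SamplerBank, priorities: dict):
    """Generator driving one patient through a pathway on the engine."""
    suite = None
    for op in _compile_steps(tuple(steps)):
        kind = op[0]
        if kind == "seize":
            needs = op[2]
            if needs is None:
                needs = {(suite if n == SUITE else n): u for n, u in op[1]}
            yield ("seize", needs, priorities[entity.patient_class], op[3])
        elif kind == "timeout":
            yield ("timeout", ctx.duration(op[1]))
        elif kind == "release":
            needs = op[2]
            if needs is None:
                needs = {(suite if n == SUITE else n): u for n, u in op[1]}
            yield ("release", needs)
        elif kind == "branch":
            if ctx.uniform(op[1]) >= ctx.branch_probs[op[1]]:
                return
        elif kind == "set_class":
            entity.patient_class = op[1]
        elif kind == "route":
            suite = yield ("route", op[1])
        else:  # exit
            return


# ---------------------------------------------------------------------------
# the assembled model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ECRModel:
    """Parameters plus resources; scenario transforms produce edited copies."""

    params: ModelParams = field(default_factory=ModelParams)
    resources: tuple = ()

    def __post_init__(self) -> None:
        if not self.resources:
            object.__setattr__(self, "resources", tuple(default_resources()))
        else:
            object.__setattr__(self, "resources", tuple(self.resources))

    @classmethod
    def default(cls, params: Optional[ModelParams] = None) -> "ECRModel":
        return cls(params=params or ModelParams())

    def resource(self, name: str) -> ResourceSpec:
        for r in self.resources:
            if r.name == name:
                return r
        raise ConfigurationError(f"unknown resource '{name}'")

    @property
    def suite_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.resources if r.kind == "suite")

    def with_resources(self, resources) -> "ECRModel":
        return ECRModel(params=self.params, resources=tuple(resources))

    def with_params(self, **changes) -> "ECRModel":
        return ECRModel(params=replace(self.params, **changes), resources=self.resources)

    # -- assembly -----------------------------------------------------------

    def build(self) -> ModelDefinition:
        p = self.params
        res = list(self.resources)
        priorities = dict(p.priorities)
        streams: list[StreamDef] = []

        def factory_for(steps):
            def factory(entity, ctx):
                return execute_pathway(entity, steps, ctx, priorities)
            return factory

        if p.independent_streams or not p.background_ed:
            # funnel fed directly by a suspected-stroke stream
            stroke_steps = build_stroke_pathway(p, res, from_suspected=True)
            ia_susp = p.interarrival("suspected_stroke")
            streams.append(StreamDef("suspected_stroke", "ed_other", ia_susp,
                                     factory_for(stroke_steps)))
            if p.background_ed:
                bg = build_background_ed_pathway()
                streams.append(StreamDef("ed", "ed_other", p.interarrival("ed"),
                                         factory_for(bg)))
        else:
            stroke_steps = build_stroke_pathway(p, res, from_suspected=False)
            streams.append(StreamDef("ed", "ed_other", p.interarrival("ed"),
                                     factory_for(stroke_steps)))

        for cls_name in ("elective_inr", "emergency_ir", "elective_ir"):
            steps = build_angio_pathway(cls_name, res)
            streams.append(StreamDef(cls_name, cls_name, p.interarrival(cls_name),
                                     factory_for(steps)))

        branch_probs = p.branch_probs()
        durations = dict(p.durations)

        def make_context(bank: RngBank) -> SamplerBank:
            return SamplerBank(bank, durations, branch_probs)

        return ModelDefinition(
            resources=tuple(res),
            streams=tuple(streams),
            gate=tuple(p.gate),
            make_context=make_context,
        )

    def simulate(
        self,
        horizon: float,
        seed: int,
        *,
        replication_id: int = 0,
        scenario_name: str = "baseline",
    ):
        """Run one replication and return the event log."""
        return engine_run(
            self.build(),
            horizon,
            seed,
            replication_id=replication_id,
            scenario_name=scenario_name,
        )
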