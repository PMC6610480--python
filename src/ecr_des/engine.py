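"""Minimal discrete event simulation kernel.

The kernel provides exactly what a hospital patient-flow model needs and no
more: a simulation clock in minutes, a future-event calendar, entities that
execute generator-based processes, resources with a daily-repeating capacity
schedule, non-preemptive priority queues with FIFO order within a priority
class, atomic AND-seizure of resource bundles (the entity waits until every
requested resource is simultaneously free, holding none meanwhile), and a
flat event log from which all outcome measures derive.

Process protocol
----------------
A process is a Python generator attached to an :class:`Entity`.  It yields
command tuples to the engine and receives results back through ``send``::

    ("seize",  {resource_name: units}, priority, gated)  ->  wait minutes
    ("timeout", duration_minutes)                        ->  None
    ("release", {resource_name: units})                  ->  None
    ("route",  (candidate_name, ...))                    ->  chosen name

``gated`` marks requests that may only *start* service inside the daily
work-hours window (elective procedures); queueing outside the window is
allowed.  Service in progress is never preempted: a capacity drop at a shift
change simply blocks new grants until the busy count falls below the new
capacity, and a higher-priority arrival jumps the queue but must wait for
the resource to be vacated.

Determinism: the engine draws no random numbers itself (arrival times and
service durations are supplied by the model layer from named streams), the
event calendar breaks time ties by insertion order, and all queue tie-breaks
are by (priority, enqueue order).  Identical definition + horizon + seed
therefore yields an identical event log.
"""

from __future__ import annotations

import heapq
import zlib
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    ConsistencyError,
    EligibilityError,
    RoutingError,
    ScheduleError,
)

MINUTES_PER_DAY = 1440.0

# event-log actions
ARRIVE = "arrive"
QUEUE_ENTER = "queue_enter"
SEIZE = "seize"
RELEASE = "release"
EXIT = "exit"

#: floating-point grants at the same instant count as "no wait"
ZERO_WAIT_TOLERANCE = 1e-9


# ---------------------------------------------------------------------------
# schedules and resource specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CapacitySchedule:
    """Daily-repeating step function giving a resource's maximum occupancy.

    ``segments`` is an ordered tuple of ``(start_minute_of_day,
    end_minute_of_day, capacity)`` that must tile ``[0, 1440)`` exactly,
    with integer capacities >= 0.
    """

    segments: tuple[tuple[float, float, int], ...]

    def __post_init__(self) -> None:
        segs = tuple((float(s), float(e), int(c)) for s, e, c in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ScheduleError("schedule has no segments")
        if segs[0][0] != 0.0 or segs[-1][1] != MINUTES_PER_DAY:
            raise ScheduleError(f"segments must tile [0, 1440): got {segs}")
        prev_end = 0.0
        for s, e, c in segs:
            if s != prev_end:
                raise ScheduleError(f"gap or overlap at minute {s} (expected {prev_end})")
            if e <= s:
                raise ScheduleError(f"empty or inverted segment ({s}, {e})")
            if c < 0:
                raise ScheduleError(f"negative capacity {c} in segment ({s}, {e})")
            prev_end = e

    @classmethod
    def constant(cls, capacity: int) -> "CapacitySchedule":
        return cls(((0.0, MINUTES_PER_DAY, int(capacity)),))

    @classmethod
    def day_night(
        cls,
        day_capacity: int,
        night_capacity: int,
        day_start: float = 480.0,
        day_end: float = 1020.0,
    ) -> "CapacitySchedule":
        """Shift staffing: ``day_capacity`` on [day_start, day_end), night otherwise."""
        if day_capacity == night_capacity:
            return cls.constant(day_capacity)
        segs = []
        if day_start > 0:
            segs.append((0.0, day_start, night_capacity))
        segs.append((day_start, day_end, day_capacity))
        if day_end < MINUTES_PER_DAY:
            segs.append((day_end, MINUTES_PER_DAY, night_capacity))
        return cls(tuple(segs))

    def capacity_at(self, t: float) -> int:
        """Capacity of the segment containing ``t mod 1440``."""
        m = t % MINUTES_PER_DAY
        for s, e, c in self.segments:
            if s <= m < e:
                return c
        return self.segments[-1][2]  # unreachable for a valid schedule

    @property
    def max_capacity(self) -> int:
        return max(c for _, _, c in self.segments)

    def minute_table(self) -> list[int]:
        """Capacity per integer minute of day, for O(1) lookups."""
        table = [0] * int(MINUTES_PER_DAY)
        for s, e, c in self.segments:
            for m in range(int(s), int(e)):
                table[m] = c
        return table

    def increase_points(self) -> list[float]:
        """Minutes of day at which capacity rises relative to the previous segment."""
        segs = self.segments
        points = []
        for i, (s, _, c) in enumerate(segs):
            prev_c = segs[i - 1][2]  # i == 0 wraps to the last (previous day) segment
            if c > prev_c:
                points.append(s)
        return points

    def capacity_minutes(self, t0: float, t1: float) -> float:
        """Integral of capacity over simulated time [t0, t1]."""

        def integral(t: float) -> float:
            days, rem = divmod(t, MINUTES_PER_DAY)
            per_day = sum(c * (e - s) for s, e, c in self.segments)
            partial = sum(
                c * max(0.0, min(e, rem) - s) for s, e, c in self.segments if s < rem
            )
            return days * per_day + partial

        return integral(t1) - integral(t0)


@dataclass(frozen=True)
class ResourceSpec:
    """A named, schedulable pool (suite, scanner or staff group).

    ``eligible_classes`` lists the patient classes permitted to seize the
    pool.  ``kind`` tags the pool's role for routing and scenario edits
    ("suite", "physician", "staff", "other"); ``human`` marks staffed pools
    whose day shift an extended-hours scenario lengthens.
    """

    name: str
    schedule: CapacitySchedule
    eligible_classes: frozenset[str]
    kind: str = "other"
    human: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "eligible_classes", frozenset(self.eligible_classes))
        if not self.eligible_classes:
            raise ConfigurationError(f"resource '{self.name}' has no eligible classes")

    def replace(self, **kw) -> "ResourceSpec":
        data = dict(
            name=self.name,
            schedule=self.schedule,
            eligible_classes=self.eligible_classes,
            kind=self.kind,
            human=self.human,
        )
        data.update(kw)
        return ResourceSpec(**data)


# ---------------------------------------------------------------------------
# model definition handed to run()
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StreamDef:
    """A Poisson arrival source feeding one process pathway.

    ``factory(entity, ctx)`` must return the process generator for a newly
    arrived entity; ``ctx`` is whatever ``ModelDefinition.make_context``
    builds from the replication's random-number bank.
    """

    name: str
    patient_class: str
    interarrival_min: Optional[float]  # None or <= 0 means a silent source
    factory: Callable


@dataclass(frozen=True)
class ModelDefinition:
    resources: tuple[ResourceSpec, ...]
    streams: tuple[StreamDef, ...]
    gate: tuple[float, float] = (480.0, 1020.0)
    make_context: Optional[Callable] = None


# ---------------------------------------------------------------------------
# random-number bank: named, seed-derived streams
# ---------------------------------------------------------------------------

class RngBank:
    """Independent named random streams derived from one root seed.

    Stream identity is stable across runs and platforms: the child seed is
    ``SeedSequence([root_seed, crc32(name)])``, so adding or removing one
    stream never perturbs another (common-random-numbers discipline across
    scenario comparisons).
    """

    def __init__(self, seed: int):
        self.seed = int(seed) & 0x7FFFFFFF
        self._rngs: dict[str, np.random.Generator] = {}

    def rng(self, name: str) -> np.random.Generator:
        g = self._rngs.get(name)
        if g is None:
            ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
            g = np.random.Generator(np.random.PCG64(ss))
            self._rngs[name] = g
        return g


def arrival_times(rng: np.random.Generator, interarrival_min: float, horizon: float) -> np.ndarray:
    """Strictly increasing Poisson-process arrival times truncated at the horizon."""
    if interarrival_min is None or interarrival_min <= 0 or not np.isfinite(interarrival_min):
        return np.empty(0)
    expected = horizon / interarrival_min
    times: list[np.ndarray] = []
    total = 0.0
    while total < horizon:
        n = int(expected - total / interarrival_min + 6.0 * np.sqrt(expected) + 64)
        gaps = rng.exponential(interarrival_min, size=n)
        chunk = total + np.cumsum(gaps)
        times.append(chunk)
        total = chunk[-1]
    t = np.concatenate(times)
    return t[t < horizon]


# ---------------------------------------------------------------------------
# runtime objects
# ---------------------------------------------------------------------------

class Entity:
    """A simulated patient: class, timestamps and currently held units."""

    __slots__ = ("id", "patient_class", "created_at", "gen", "holding")

    def __init__(self, eid: int, patient_class: str, created_at: float):
        self.id = eid
        self.patient_class = patient_class
        self.created_at = created_at
        self.gen = None
        self.holding: dict[str, int] = {}


class _Request:
    __slots__ = ("entity", "needs", "priority", "enqueued_at", "seq", "gated", "granted")

    def __init__(self, entity, needs, priority, enqueued_at, seq, gated):
        self.entity = entity
        self.needs = needs  # tuple of (_ResourceState, units)
        self.priority = priority
        self.enqueued_at = enqueued_at
        self.seq = seq
        self.gated = gated
        self.granted = False


class _ResourceState:
    __slots__ = ("spec", "name", "idx", "busy", "queue", "waiting", "cap_min", "eligible", "max_cap")

    def __init__(self, spec: ResourceSpec, idx: int):
        self.spec = spec
        self.name = spec.name
        self.idx = idx
        self.busy = 0
        self.queue: list = []  # heap of (priority, seq, _Request)
        self.waiting = 0
        self.cap_min = spec.schedule.minute_table()
        self.eligible = spec.eligible_classes
        self.max_cap = spec.schedule.max_capacity


# event kinds on the calendar
_ARRIVAL = 0
_PROC = 1
_WAKE = 2


@dataclass
class EventLog:
    """Flat record of every arrival, queue entry, seize, release and exit.

    ``records`` rows are ``(time_min, entity_id, patient_class, resource,
    action, queue_length, units)``; ``queue_length`` counts *other* requests
    waiting at that resource at the instant of the record.  Rows are in
    processing order, which is time order with ties broken by insertion.
    Entities still queued or in service at the horizon are listed in
    ``incomplete_ids`` and excluded from wait statistics downstream.
    """

    records: list
    replication_id: int
    seed: int
    scenario_name: str
    horizon: float
    incomplete_ids: frozenset
    resource_names: tuple[str, ...]
    known_classes: frozenset
    stream_counts: dict[str, int] = field(default_factory=dict)

    COLUMNS = (
        "time_min", "replication", "scenario", "entity_id",
        "patient_class", "resource", "action", "queue_length",
    )

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            self.records,
            columns=["time_min", "entity_id", "patient_class", "resource", "action",
                     "queue_length", "units"],
        )
        df.insert(1, "replication", self.replication_id)
        df.insert(2, "scenario", self.scenario_name)
        return df

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df[list(self.COLUMNS)].to_csv(path, index=False)


class Engine:
    """Simulation clock, event calendar and resource state for one replication."""

    def __init__(
        self,
        resources: Sequence[ResourceSpec],
        horizon: float,
        *,
        gate: tuple[float, float] = (480.0, 1020.0),
        scenario_name: str = "baseline",
        replication_id: int = 0,
        seed: int = 0,
    ):
        if horizon <= 0:
            raise ConfigurationError("horizon must be positive")
        names = [r.name for r in resources]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate resource names in {names}")
        if not resources:
            raise ConfigurationError("at least one resource is required")
        self.horizon = float(horizon)
        self.gate = (float(gate[0]), float(gate[1]))
        self.scenario_name = scenario_name
        self.replication_id = replication_id
        self.seed = seed
        self.now = 0.0
        self._heap: list = []
        self._needs_heapify = False
        self._seq = 0
        self._next_eid = 0
        self.records: list = []
        self._active: dict[int, Entity] = {}
        self._states = [_ResourceState(r, i) for i, r in enumerate(resources)]
        self._rmap = {s.name: s for s in self._states}
        self.stream_counts: dict[str, int] = {}
        self._schedule_wakes()

    # -- calendar ----------------------------------------------------------

    def _push(self, t: float, kind: int, a, b) -> None:
        self._seq += 1
        heapq.heappush(self._heap, (t, self._seq, kind, a, b))

    def _schedule_wakes(self) -> None:
        """Wake the queues at capacity increases and at the daily gate opening."""
        points = {self.gate[0] % MINUTES_PER_DAY}
        for s in self._states:
            points.update(s.spec.schedule.increase_points())
        ndays = int(self.horizon // MINUTES_PER_DAY) + 1
        for m in sorted(points):
            for d in range(ndays):
                t = m + d * MINUTES_PER_DAY
                if 0.0 < t < self.horizon:
                    self._push(t, _WAKE, None, None)

    # -- public API used by the model layer --------------------------------

    def schedule_arrival(self, t: float, patient_class: str, factory, stream_name: str) -> None:
        if t >= self.horizon:
            return
        self._seq += 1
        self._heap.append((t, self._seq, _ARRIVAL, patient_class, (factory, stream_name)))
        self._needs_heapify = True
        self.stream_counts[stream_name] = self.stream_counts.get(stream_name, 0) + 1

    def run_until(self, until: Optional[float] = None) -> None:
        until = self.horizon if until is None else min(until, self.horizon)
        if self._needs_heapify:
            heapq.heapify(self._heap)
            self._needs_heapify = False
        heap = self._heap
        while heap:
            t = heap[0][0]
            if t >= until:
                break
            t, _seq, kind, a, b = heapq.heappop(heap)
            self.now = t
            if kind == _PROC:
                self._advance(a, b)
            elif kind == _ARRIVAL:
                factory, _stream = b
                ent = Entity(self._next_eid, a, t)
                self._next_eid += 1
                self._active[ent.id] = ent
                self.records.append((t, ent.id, ent.patient_class, "", ARRIVE, 0, 0))
                ent.gen = factory(ent)
                self._advance(ent, None)
            else:  # _WAKE
                self._pump()
        self.now = until

    def finish(self) -> EventLog:
        known = set()
        for s in self._states:
            known |= s.eligible
        return EventLog(
            records=self.records,
            replication_id=self.replication_id,
            seed=self.seed,
            scenario_name=self.scenario_name,
            horizon=self.horizon,
            incomplete_ids=frozenset(self._active),
            resource_names=tuple(s.name for s in self._states),
            known_classes=frozenset(known),
            stream_counts=dict(self.stream_counts),
        )

    def queue_length(self, resource: str) -> int:
        return self._rmap[resource].waiting

    def gate_open(self, t: float) -> bool:
        m = t % MINUTES_PER_DAY
        g0, g1 = self.gate
        return g0 <= m < g1

    # -- process driver -----------------------------------------------------

    def _advance(self, ent: Entity, value) -> None:
        gen = ent.gen
        records = self.records
        while True:
            try:
                cmd = gen.send(value)
            except StopIteration:
                records.append((self.now, ent.id, ent.patient_class, "", EXIT, 0, 0))
                self._active.pop(ent.id, None)
                return
            op = cmd[0]
            if op == "timeout":
                self._push(self.now + cmd[1], _PROC, ent, None)
                return
            if op == "seize":
                granted = self._seize(ent, cmd[1], cmd[2], cmd[3] if len(cmd) > 3 else False)
                if granted:
                    value = 0.0
                    continue
                return  # resumed by the grant
            if op == "release":
                self._release(ent, cmd[1])
                value = None
                continue
            if op == "route":
                value = self.select_resource(cmd[1], ent)
                continue
            raise ConsistencyError(f"unknown process command {cmd!r}")

    # -- seize / release / routing -----------------------------------------

    def _seize(self, ent: Entity, needs: dict, priority: int, gated: bool) -> bool:
        now = self.now
        rs = []
        for name, units in needs.items():
            state = self._rmap.get(name)
            if state is None:
                raise ConfigurationError(f"pathway references unknown resource '{name}'")
            if ent.patient_class not in state.eligible:
                raise EligibilityError(
                    f"class '{ent.patient_class}' is not eligible for resource '{name}'"
                )
            units = int(units)
            if units < 1 or units > state.max_cap:
                raise ConfigurationError(
                    f"requested {units} units of '{name}' "
                    f"(scheduled maximum {state.max_cap})"
                )
            rs.append((state, units))
        records = self.records
        minute = int(now % MINUTES_PER_DAY)
        # fast path: nobody waiting anywhere in the bundle and all units free
        if not gated or self.gate_open(now):
            ok = True
            for state, units in rs:
                if state.waiting or state.busy + units > state.cap_min[minute]:
                    ok = False
                    break
            if ok:
                cls = ent.patient_class
                eid = ent.id
                holding = ent.holding
                for state, units in rs:
                    records.append((now, eid, cls, state.name, QUEUE_ENTER, state.waiting, units))
                    state.busy += units
                    holding[state.name] = holding.get(state.name, 0) + units
                    records.append((now, eid, cls, state.name, SEIZE, state.waiting, units))
                return True
        # slow path: join every queue in the bundle, then try to pump
        self._seq += 1
        req = _Request(ent, tuple(rs), priority, now, self._seq, gated)
        key = (priority, req.seq)
        for state, units in rs:
            records.append((now, ent.id, ent.patient_class, state.name, QUEUE_ENTER, state.waiting, units))
            heapq.heappush(state.queue, (key[0], key[1], req))
            state.waiting += 1
        self._pump([state for state, _ in rs])
        return False

    def _release(self, ent: Entity, needs: dict) -> None:
        records = self.records
        released = []
        for name, units in needs.items():
            state = self._rmap.get(name)
            if state is None:
                raise ConfigurationError(f"release references unknown resource '{name}'")
            units = int(units)
            held = ent.holding.get(name, 0)
            if held < units:
                raise ConsistencyError(
                    f"entity {ent.id} released {units} units of '{name}' but holds {held}"
                )
            if held == units:
                del ent.holding[name]
            else:
                ent.holding[name] = held - units
            state.busy -= units
            released.append(state)
            records.append((self.now, ent.id, ent.patient_class, name, RELEASE, state.waiting, units))
        self._pump(released)

    def select_resource(self, candidates: Iterable[str], ent: Entity) -> str:
        """Shortest-queue routing; ties broken by fixed declaration order."""
        best = None
        for name in candidates:
            state = self._rmap.get(name)
            if state is None:
                raise ConfigurationError(f"routing references unknown resource '{name}'")
            if ent.patient_class not in state.eligible:
                continue
            key = (state.waiting, state.idx)
            if best is None or key < best[0]:
                best = (key, state.name)
        if best is None:
            raise RoutingError(
                f"no eligible resource among {list(candidates)} for class '{ent.patient_class}'"
            )
        return best[1]

    # -- grant machinery ----------------------------------------------------

    def _peek(self, state: _ResourceState):
        q = state.queue
        while q and q[0][2].granted:
            heapq.heappop(q)
        return q[0][2] if q else None

    def _grantable(self, req: _Request, minute: int) -> bool:
        if req.gated and not self.gate_open(self.now):
            return False
        for state, units in req.needs:
            if state.busy + units > state.cap_min[minute]:
                return False
            if self._peek(state) is not req:
                return False
        return True

    def _grant(self, req: _Request) -> None:
        req.granted = True
        ent = req.entity
        now = self.now
        records = self.records
        for state, units in req.needs:
            state.busy += units
            state.waiting -= 1
            ent.holding[state.name] = ent.holding.get(state.name, 0) + units
            records.append((now, ent.id, ent.patient_class, state.name, SEIZE, state.waiting, units))
        wait = now - req.enqueued_at
        self._push(now, _PROC, ent, wait if wait > ZERO_WAIT_TOLERANCE else 0.0)

    def _pump(self, dirty=None) -> None:
        """Grant every request that is at the head of all its queues and fits.

        Strict head-of-line discipline per resource: if the head (highest
        priority, earliest enqueue) cannot start — a bundle partner busy, a
        shift drop, a closed elective gate — nothing behind it on that
        resource starts either.  This is what makes the priority and FIFO
        invariants hold by construction.

        ``dirty`` limits the scan to resources whose state just changed.
        This is sufficient: a bundle request occupies *every* queue it
        needs, so whichever of its resources freed up will surface it as
        that queue's head.  Simultaneously grantable requests are disjoint
        (two requests sharing a resource cannot both head its queue), so
        the scan order cannot change who is granted, only the record order,
        which is kept canonical by sorting on declaration order.
        """
        minute = int(self.now % MINUTES_PER_DAY)
        work = self._states if dirty is None else dirty
        while work:
            next_work: dict = {}
            for state in sorted(work, key=lambda s: s.idx) if dirty is not None else work:
                if not state.waiting:
                    continue
                req = self._peek(state)
                if req is not None and self._grantable(req, minute):
                    self._grant(req)
                    for s, _u in req.needs:
                        next_work[s] = None
            work = list(next_work)
            dirty = work


# ---------------------------------------------------------------------------
# top-level run
# ---------------------------------------------------------------------------

def run(
    definition: ModelDefinition,
    horizon: float,
    seed: int,
    *,
    replication_id: int = 0,
    scenario_name: str = "baseline",
) -> EventLog:
    """Simulate one replication of ``definition`` and return the event log.

    Identical ``(definition, horizon, seed)`` yields an identical log.  Each
    arrival source and each duration sampler draws from its own named stream
    derived from ``seed`` (see :class:`RngBank`), so two scenarios run with
    the same seed share arrival times — common random numbers.
    """
    if not definition.streams:
        raise ConfigurationError("model definition has no arrival sources")
    eng = Engine(
        definition.resources,
        horizon,
        gate=definition.gate,
        scenario_name=scenario_name,
        replication_id=replication_id,
        seed=seed,
    )
    bank = RngBank(seed)
    ctx = definition.make_context(bank) if definition.make_context else bank
    for stream in definition.streams:
        times = arrival_times(bank.rng("arr:" + stream.name), stream.interarrival_min, horizon)
        eng.stream_counts.setdefault(stream.name, 0)
        factory = stream.factory

        def make(ent, _factory=factory, _ctx=ctx):
            return _factory(ent, _ctx)

        for t in times:
            eng.schedule_arrival(float(t), stream.patient_class, make, stream.name)
    eng.run_until(horizon)
    return eng.finish()
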