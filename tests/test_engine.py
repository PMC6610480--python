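"""Kernel semantics: schedules, priority queues, AND-seize, conservation."""

import numpy as np
import pytest

from conftest import job_factory, make_engine

from ecr_des.engine import (
    CapacitySchedule,
    Engine,
    ModelDefinition,
    ResourceSpec,
    SEIZE,
    RELEASE,
    StreamDef,
    run,
)
from ecr_des.errors import (
    ConfigurationError,
    ConsistencyError,
    EligibilityError,
    RoutingError,
    ScheduleError,
)


# ---------------------------------------------------------------------------
# capacity schedules
# ---------------------------------------------------------------------------

class TestCapacitySchedule:
    def test_day_night_lookup(self):
        # interventional radiologist roster: 2 on days (08:00-17:00), 1 at night
        ir = CapacitySchedule.day_night(2, 1)
        assert ir.capacity_at(10 * 60) == 2
        assert ir.capacity_at(3 * 60) == 1
        assert ir.capacity_at(17 * 60) == 1  # boundary belongs to the night segment
        assert ir.capacity_at(8 * 60) == 2
        # repeats daily
        assert ir.capacity_at(3 * 1440 + 10 * 60) == 2

    def test_constant(self):
        const = CapacitySchedule.constant(1)
        for t in (0.0, 719.5, 1439.9, 99_999.0):
            assert const.capacity_at(t) == 1

    @pytest.mark.parametrize(
        "segments",
        [
            ((0.0, 1000.0, 1),),                       # does not reach 1440
            ((100.0, 1440.0, 1),),                     # does not start at 0
            ((0.0, 800.0, 1), (900.0, 1440.0, 1)),     # gap
            ((0.0, 800.0, 1), (700.0, 1440.0, 1)),     # overlap
            ((0.0, 1440.0, -2),),                      # negative capacity
        ],
    )
    def test_invalid_schedules_rejected(self, segments):
        with pytest.raises(ScheduleError):
            CapacitySchedule(segments)

    def test_capacity_minutes_integrates_shifts(self):
        ir = CapacitySchedule.day_night(2, 1)
        # one day: 9h * 2 + 15h * 1 = 1980 capacity-minutes
        assert ir.capacity_minutes(0, 1440) == pytest.approx(1980.0)
        assert ir.capacity_minutes(0, 10 * 1440) == pytest.approx(19_800.0)
        # partial window inside the day shift
        assert ir.capacity_minutes(480, 540) == pytest.approx(120.0)


# ---------------------------------------------------------------------------
# run-level contracts
# ---------------------------------------------------------------------------

def _one_server_definition(rate_interarrival):
    res = ResourceSpec("server", CapacitySchedule.constant(1), frozenset({"job"}))
    stream = StreamDef("jobs", "job", rate_interarrival,
                       lambda ent, ctx: job_factory(5.0)(ent))
    return ModelDefinition(resources=(res,), streams=(stream,))


def test_rate_zero_source_yields_empty_log():
    log = run(_one_server_definition(None), horizon=10_000.0, seed=3)
    assert len(log.records) == 0
    assert log.stream_counts == {"jobs": 0}


def test_identical_seeds_identical_logs():
    defn = _one_server_definition(7.0)
    log_a = run(defn, horizon=5_000.0, seed=42)
    log_b = run(defn, horizon=5_000.0, seed=42)
    assert log_a.records == log_b.records
    log_c = run(defn, horizon=5_000.0, seed=43)
    assert log_c.records != log_a.records


def test_unknown_resource_named_in_error():
    res = ResourceSpec("server", CapacitySchedule.constant(1), frozenset({"job"}))
    stream = StreamDef("jobs", "job", 10.0,
                       lambda ent, ctx: job_factory(1.0, needs={"ghost": 1})(ent))
    with pytest.raises(ConfigurationError, match="ghost"):
        run(ModelDefinition(resources=(res,), streams=(stream,)), horizon=100.0, seed=0)


# ---------------------------------------------------------------------------
# seize / release semantics
# ---------------------------------------------------------------------------

def _scripted(engine, arrivals, services, priorities, needs=None, cls="job"):
    for i, (t, s, p) in enumerate(zip(arrivals, services, priorities)):
        engine.schedule_arrival(float(t), cls, job_factory(float(s), needs=needs, priority=p),
                                "jobs")
    engine.run_until()
    return engine.finish()


def _service_order(log, resource="server"):
    return [eid for (_, eid, _, res, action, _, _) in log.records
            if res == resource and action == SEIZE]


def test_idle_resource_grants_immediately(single_server):
    eng = make_engine([single_server])
    log = _scripted(eng, [3.0], [5.0], [0])
    seizes = [(t, a) for (t, _, _, _, a, _, _) in log.records if a == SEIZE]
    assert seizes == [(3.0, SEIZE)]


def test_emergencies_jump_a_queue_of_electives(single_server):
    """Ten electives queue; a stroke and an emergency IR patient arrive later.

    After the patient already in service, the order must be: stroke first,
    then emergency IR, then the electives in FIFO order.
    """
    eng = make_engine([single_server])
    arrivals = list(range(10)) + [20, 21]          # 10 electives, then the emergencies
    services = [30.0] * 12
    priorities = [2] * 10 + [1, 0]                 # last arrival is the stroke
    log = _scripted(eng, arrivals, services, priorities)
    order = _service_order(log)
    # entity ids follow arrival order: 0..9 electives, 10 emergency IR, 11 stroke
    assert order[0] == 0                           # already in service when they arrive
    assert order[1] == 11                          # stroke
    assert order[2] == 10                          # emergency IR
    assert order[3:] == [1, 2, 3, 4, 5, 6, 7, 8, 9]  # electives FIFO


def test_fifo_within_equal_priority(single_server):
    eng = make_engine([single_server])
    log = _scripted(eng, [0.0, 1.0, 2.0], [10.0, 5.0, 5.0], [1, 1, 1])
    assert _service_order(log) == [0, 1, 2]


def test_release_hands_over_at_same_instant(single_server):
    eng = make_engine([single_server])
    log = _scripted(eng, [0.0, 1.0], [5.0, 5.0], [0, 0])
    events = [(t, eid, a) for (t, eid, _, r, a, _, _) in log.records
              if r == "server" and a in (SEIZE, RELEASE)]
    assert (5.0, 0, RELEASE) in events
    assert (5.0, 1, SEIZE) in events


def test_shift_drop_blocks_new_grants_until_busy_below_capacity():
    """Capacity drops 2 -> 1 mid-service; both services finish, but the queued
    job starts only when the busy count falls below the new capacity."""
    staff = ResourceSpec("staff", CapacitySchedule.day_night(2, 1, 0.0, 100.0),
                         frozenset({"job"}))
    eng = make_engine([staff], horizon=1440.0)
    # two jobs seize before the drop at t=100 and run past it; a third queues at t=60
    log = _scripted(eng, [0.0, 0.0, 60.0], [110.0, 150.0, 10.0], [0, 0, 0],
                    needs={"staff": 1})
    grants = {eid: t for (t, eid, _, r, a, _, _) in log.records
              if r == "staff" and a == SEIZE}
    # job 0 releases at t=110 (busy 2 -> 1, equal to the new capacity: no free
    # unit); job 1 releases at t=150 (busy 0 < 1) and only then job 2 starts
    assert grants[2] == 150.0


def test_release_unheld_raises_consistency_error(single_server):
    eng = make_engine([single_server])

    def bad(_entity):
        yield ("release", {"server": 1})

    eng.schedule_arrival(0.0, "job", bad, "jobs")
    with pytest.raises(ConsistencyError):
        eng.run_until()


def test_ineligible_class_rejected(single_server):
    eng = make_engine([single_server])
    eng.schedule_arrival(0.0, "intruder", job_factory(1.0), "jobs")
    with pytest.raises(EligibilityError):
        eng.run_until()


# ---------------------------------------------------------------------------
# AND-seize bundles
# ---------------------------------------------------------------------------

def _two_resource_engine():
    a = ResourceSpec("suite", CapacitySchedule.constant(1), frozenset({"job"}))
    b = ResourceSpec("doctor", CapacitySchedule.constant(1), frozenset({"job"}))
    return make_engine([a, b])


def test_bundle_holds_nothing_while_waiting():
    """A bundle request blocked on one resource must not occupy the other."""
    eng = _two_resource_engine()
    # job 0 occupies only the doctor; job 1 wants suite+doctor; job 2 wants suite only
    eng.schedule_arrival(0.0, "job", job_factory(50.0, needs={"doctor": 1}), "s")
    eng.schedule_arrival(1.0, "job", job_factory(5.0, needs={"suite": 1, "doctor": 1}), "s")
    eng.run_until()
    log = eng.finish()
    suite_busy = [(t, a) for (t, _, _, r, a, _, _) in log.records
                  if r == "suite" and a in (SEIZE, RELEASE)]
    # the suite is first seized only when the doctor frees at t=50
    assert suite_busy[0] == (50.0, SEIZE)


def test_bundle_counts_in_every_queue():
    """A waiting bundle occupies one queue slot in each requested resource."""
    eng = _two_resource_engine()
    eng.schedule_arrival(0.0, "job", job_factory(100.0, needs={"doctor": 1}), "s")
    eng.schedule_arrival(1.0, "job", job_factory(5.0, needs={"suite": 1, "doctor": 1}), "s")
    eng.run_until(10.0)
    assert eng.queue_length("suite") == 1
    assert eng.queue_length("doctor") == 1


# ---------------------------------------------------------------------------
# shortest-queue routing
# ---------------------------------------------------------------------------

class TestSelectResource:
    def _engine_with_queues(self, len_a, len_b):
        a = ResourceSpec("angio_inr", CapacitySchedule.constant(1), frozenset({"job"}))
        b = ResourceSpec("angio_ir", CapacitySchedule.constant(1), frozenset({"job"}))
        eng = make_engine([a, b])
        # occupy both servers, then queue the requested numbers behind them
        for name, extra in (("angio_inr", len_a), ("angio_ir", len_b)):
            eng.schedule_arrival(0.0, "job", job_factory(10_000.0, needs={name: 1}), "s")
            for _ in range(extra):
                eng.schedule_arrival(0.0, "job", job_factory(1.0, needs={name: 1}), "s")
        eng.run_until(1.0)
        return eng

    def test_shortest_queue_wins(self):
        eng = self._engine_with_queues(3, 1)
        ent = type("E", (), {"patient_class": "job"})()
        assert eng.select_resource(["angio_inr", "angio_ir"], ent) == "angio_ir"

    def test_tie_breaks_by_declaration_order(self):
        eng = self._engine_with_queues(2, 2)
        ent = type("E", (), {"patient_class": "job"})()
        assert eng.select_resource(["angio_inr", "angio_ir"], ent) == "angio_inr"

    def test_single_candidate(self):
        eng = self._engine_with_queues(0, 0)
        ent = type("E", (), {"patient_class": "job"})()
        assert eng.select_resource(["angio_ir"], ent) == "angio_ir"

    def test_no_eligible_candidate_raises(self):
        eng = self._engine_with_queues(0, 0)
        ent = type("E", (), {"patient_class": "alien"})()
        with pytest.raises(RoutingError):
            eng.select_resource(["angio_inr", "angio_ir"], ent)


# ---------------------------------------------------------------------------
# conservation properties
# ---------------------------------------------------------------------------

def test_conservation_and_capacity_bounds():
    """Seizes pair with releases and busy units never exceed scheduled capacity."""
    staff = ResourceSpec("staff", CapacitySchedule.day_night(3, 1, 480.0, 1020.0),
                         frozenset({"job"}))
    eng = make_engine([staff], horizon=20_000.0)
    rng = np.random.default_rng(5)
    t = 0.0
    for _ in range(400):
        t += rng.exponential(40.0)
        eng.schedule_arrival(t, "job", job_factory(float(rng.exponential(60.0)),
                                                   needs={"staff": 1},
                                                   priority=int(rng.integers(0, 3))), "s")
    eng.run_until()
    log = eng.finish()
    per_entity = {}
    busy = 0
    for (time, eid, _, res, action, _, _) in log.records:
        if res != "staff":
            continue
        if action == SEIZE:
            per_entity[eid] = per_entity.get(eid, 0) + 1
            busy += 1
            assert busy <= staff.schedule.capacity_at(time)
        elif action == RELEASE:
            per_entity[eid] = per_entity.get(eid, 0) - 1
            busy -= 1
    completed = set(per_entity) - set(log.incomplete_ids)
    assert all(per_entity[eid] == 0 for eid in completed)


def test_priority_safety_non_preemptive():
    """No grant ever passes over a strictly-higher-priority waiting request."""
    server = ResourceSpec("server", CapacitySchedule.constant(1), frozenset({"job"}))
    eng = make_engine([server], horizon=50_000.0)
    rng = np.random.default_rng(11)
    t = 0.0
    arrivals = {}
    for i in range(300):
        t += rng.exponential(8.0)
        p = int(rng.integers(0, 3))
        arrivals[i] = (t, p)
        eng.schedule_arrival(t, "job", job_factory(float(rng.exponential(9.0)),
                                                   priority=p), "s")
    eng.run_until()
    log = eng.finish()
    waiting: dict = {}
    for (time, eid, _, res, action, _, _) in log.records:
        if res != "server":
            continue
        if action == "queue_enter":
            waiting[eid] = (arrivals[eid][1], time)
        elif action == SEIZE:
            p_granted, t_enq = waiting.pop(eid)
            for other, (p_other, t_other) in waiting.items():
                assert not (p_other < p_granted and t_other < time), (
                    f"entity {eid} (priority {p_granted}) granted at {time} while "
                    f"higher-priority {other} waited since {t_other}"
                )
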