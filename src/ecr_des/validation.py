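"""Independent oracles for engine correctness.

Two kinds of oracle back the simulation kernel:

- closed-form steady-state queueing results (M/M/1 and Erlang-C M/M/c mean
  queue waits) against which long simulated runs must converge, and
- a brute-force chronological single-server stepper that computes exact
  per-entity waits for small scripted instances under non-preemptive
  priority + FIFO discipline.

Both are written independently of the event-calendar engine so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .engine import (
    CapacitySchedule,
    Engine,
    ResourceSpec,
    RngBank,
    arrival_times,
)
from .metrics import wait_times

__all__ = [
    "QueueParams",
    "mm1_mean_wait",
    "erlang_c",
    "mmc_mean_wait",
    "brute_force_waits",
    "engine_single_server_waits",
    "simulate_mmc_mean_wait",
    "validation_report",
]


@dataclass(frozen=True)
class QueueParams:
    """Arrival rate, service rate (per minute) and server count."""

    lam: float
    mu: float
    c: int = 1

    @property
    def rho(self) -> float:
        return self.lam / (self.c * self.mu)


def mm1_mean_wait(lam: float, mu: float) -> float:
    """Steady-state M/M/1 mean queue wait Wq = lam / (mu * (mu - lam))."""
    if lam >= mu:
        raise ValueError(f"unstable queue: lam={lam} >= mu={mu}")
    if lam < 0 or mu <= 0:
        raise ValueError("rates must be non-negative (mu positive)")
    return lam / (mu * (mu - lam))


def erlang_c(c: int, a: float) -> float:
    """Erlang-C probability that an arrival must wait (offered load ``a = lam/mu``)."""
    if c < 1:
        raise ValueError("need at least one server")
    if a >= c:
        raise ValueError(f"unstable queue: offered load {a} >= servers {c}")
    term = 1.0
    s = 1.0  # k = 0 term
    for k in range(1, c):
        term *= a / k
        s += term
    term *= a / c  # a^c / c!
    tail = term * c / (c - a)
    return tail / (s + tail)


def mmc_mean_wait(lam: float, mu: float, c: int) -> float:
    """Steady-state M/M/c mean queue wait: Erlang-C / (c*mu - lam)."""
    if lam >= c * mu:
        raise ValueError(f"unstable queue: lam={lam} >= c*mu={c * mu}")
    return erlang_c(c, lam / mu) / (c * mu - lam)


def brute_force_waits(
    arrival_times_: Sequence[float],
    service_times: Sequence[float],
    priorities: Optional[Sequence[int]] = None,
) -> list[float]:
    """Exact waits for one single-unit, non-preemptive priority/FIFO server.

    Direct chronological stepping with sequential-event tie semantics: an
    arrival finding the server idle starts service immediately (so two
    same-instant arrivals at an idle server are served in input order, not
    re-ranked by priority), while every arrival at or before a busy
    server's free instant competes there by (priority, arrival order).
    Ties in (priority, arrival time) resolve by input order.
    """
    n = len(arrival_times_)
    if len(service_times) != n:
        raise ValueError("arrival and service sequences must have equal length")
    prio = list(priorities) if priorities is not None else [0] * n
    if len(prio) != n:
        raise ValueError("priorities must match arrivals in length")
    order = sorted(range(n), key=lambda i: (arrival_times_[i], i))
    waits = [0.0] * n
    in_q: list = []
    ptr = 0
    busy_until: Optional[float] = None
    served = 0
    while served < n:
        if busy_until is None:
            i = order[ptr]
            ptr += 1
            waits[i] = 0.0
            busy_until = arrival_times_[i] + service_times[i]
            served += 1
        else:
            while ptr < n and arrival_times_[order[ptr]] <= busy_until:
                j = order[ptr]
                heapq.heappush(in_q, (prio[j], ptr, j))
                ptr += 1
            if in_q:
                _, _, i = heapq.heappop(in_q)
                waits[i] = busy_until - arrival_times_[i]
                busy_until += service_times[i]
                served += 1
            else:
                busy_until = None
    return waits


# ---------------------------------------------------------------------------
# engine harnesses for oracle comparison
# ---------------------------------------------------------------------------

def _single_server_resource(capacity: int = 1) -> ResourceSpec:
    return ResourceSpec(
        "server", CapacitySchedule.constant(capacity), frozenset({"job"}), kind="other"
    )


def engine_single_server_waits(
    arrivals: Sequence[float],
    services: Sequence[float],
    priorities: Optional[Sequence[int]] = None,
    *,
    capacity: int = 1,
) -> list[float]:
    """Run the scripted instance through the event-calendar engine; return waits."""
    n = len(arrivals)
    prio = list(priorities) if priorities is not None else [0] * n
    horizon = float(max(arrivals) + sum(services) + 1.0)
    eng = Engine([_single_server_resource(capacity)], horizon, scenario_name="oracle")

    def make_factory(service, p):
        def factory(_entity):
            yield ("seize", {"server": 1}, p, False)
            yield ("timeout", service)
            yield ("release", {"server": 1})

        return factory

    for i in range(n):
        eng.schedule_arrival(float(arrivals[i]), "job", make_factory(float(services[i]), prio[i]), "jobs")
    eng.run_until(horizon)
    log = eng.finish()
    df = wait_times(log, "server")
    by_entity = dict(zip(df["entity_id"], df["wait"]))
    # entity ids are assigned in arrival (time, insertion) order
    order = sorted(range(n), key=lambda i: (arrivals[i], i))
    waits = [0.0] * n
    for eid, i in enumerate(order):
        waits[i] = float(by_entity[eid])
    return waits


def simulate_mmc_mean_wait(
    lam: float,
    mu: float,
    c: int,
    *,
    horizon: float = 20_000.0,
    replications: int = 12,
    warmup: float = 2_000.0,
    seed: int = 0,
) -> tuple[float, float]:
    """Simulated M/M/c mean queue wait and its Monte-Carlo standard error.

    Runs independent replications of Poisson arrivals / exponential service
    through the engine; the standard error is across replication means, so
    within-run autocorrelation is handled by design.
    """
    rep_means = []
    for r in range(replications):
        bank = RngBank((seed << 8) ^ r)
        arr = arrival_times(bank.rng("arr"), 1.0 / lam, horizon)
        services = bank.rng("svc").exponential(1.0 / mu, size=arr.size)
        eng = Engine([_single_server_resource(c)], horizon, scenario_name="mmc")

        def make_factory(service):
            def factory(_entity):
                yield ("seize", {"server": 1}, 0, False)
                yield ("timeout", service)
                yield ("release", {"server": 1})

            return factory

        for t, s in zip(arr, services):
            eng.schedule_arrival(float(t), "job", make_factory(float(s)), "jobs")
        eng.run_until(horizon)
        log = eng.finish()
        w = wait_times(log, "server", warmup=warmup)["wait"].to_numpy()
        if w.size:
            rep_means.append(w.mean())
    rep_means = np.asarray(rep_means)
    se = rep_means.std(ddof=1) / math.sqrt(rep_means.size) if rep_means.size > 1 else float("inf")
    return float(rep_means.mean()), float(se)


def validation_report(seed: int = 0, *, n_random_instances: int = 100) -> list[dict]:
    """Pass/fail table of engine-vs-oracle checks (used by the CLI and tests)."""
    rows = []
    # closed-form convergence at three traffic intensities, one and two servers
    for c in (1, 2):
        for rho in (0.3, 0.6, 0.9):
            lam, mu = rho * c, 1.0
            target = mmc_mean_wait(lam, mu, c)
            est, se = simulate_mmc_mean_wait(lam, mu, c, seed=seed)
            rows.append(
                {
                    "check": f"M/M/{c} Wq at rho={rho}",
                    "expected": target,
                    "observed": est,
                    "tolerance": 3.0 * se,
                    "passed": abs(est - target) <= 3.0 * se,
                }
            )
    # exact agreement with the brute-force priority oracle on random instances
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_random_instances):
        n = int(rng.integers(1, 21))
        arrivals = np.sort(rng.integers(0, 40, size=n)).astype(float)
        services = rng.integers(1, 10, size=n).astype(float)
        prios = rng.integers(0, 3, size=n)
        expected = brute_force_waits(arrivals, services, prios)
        observed = engine_single_server_waits(arrivals, services, prios)
        if any(abs(a - b) > 1e-9 for a, b in zip(expected, observed)):
            mismatches += 1
    rows.append(
        {
            "check": f"brute-force oracle agreement ({n_random_instances} instances)",
            "expected": 0,
            "observed": mismatches,
            "tolerance": 0,
            "passed": mismatches == 0,
        }
    )
    return rows
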