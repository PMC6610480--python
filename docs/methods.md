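# Methods

## The model

`ecr_des` is a discrete event simulation (DES) of a comprehensive stroke
service delivering endovascular clot retrieval (ECR, mechanical
thrombectomy) alongside the elective and emergency interventional workload
that shares its angiography resources.  Entities are patients; resources are
pools of physical assets (a biplane angioINR suite, a single-plane angioIR
suite, two CT scanners) and staffed groups with shift schedules (one
interventional neuroradiologist, 2/1 interventional radiologists day/night,
6/3 angiography staff, a 10-person ED team, one stroke team).  Between
events nothing changes; the clock jumps from event to event.

Four pathways compete for these pools:

1. **Stroke**: ED triage → stroke-team assessment → CT → eligibility →
   ECR, which atomically seizes {angioINR suite, INR, 1 angio staff}.
2. **Elective INR**: staff prep → {angioINR, INR, staff} procedure.
3. **Emergency IR**: staff prep → procedure on whichever suite has the
   shortest queue (angioINR or angioIR), with an IR.
4. **Elective IR**: as emergency IR, but at elective priority.

### Arrivals and the stroke funnel

Every stream is a homogeneous Poisson process whose mean interarrival time
is 525,600 minutes divided by the annual case count (e.g. 3,805 elective IR
cases → 138 min).  The stroke pathway is fed by the raw ED stream
(107,700 presentations/yr, one every ~5 min); progression is Bernoulli at
branch probabilities equal to ratios of the annual counts —
P(suspected stroke | ED) = 750/107,700, P(AIS | suspected) = 450/750,
P(ECR | AIS) = 58/450 — so the downstream annual rates (750, 450, 58) are
emergent expectations rather than independent generators, consistent with a
single ED entry point.  ED presentations that leave the funnel still contend
for the ED team during triage, which is their only coupling to the rest of
the service; `background_ed=False` replaces the raw ED stream with a
direct suspected-stroke stream (a thinned Poisson process, statistically
identical for the funnel) when that contention is not of interest, and
`independent_streams=True` keeps both.

### Queue discipline

Queues are non-preemptive priority queues: stroke (0) ahead of emergency IR
(1) ahead of all electives (2), FIFO within a class.  A higher-priority
request jumps the queue but never interrupts a service in progress.
Procedure steps seize their resource bundle atomically: the patient waits
until suite, physician and staff are simultaneously free and holds nothing
meanwhile, which eliminates deadlock by construction.  A waiting bundle
occupies one queue slot in each requested resource's queue; this is a
declared convention (it affects shortest-queue routing counts and is
tested), not an empirically derived one.  When several suites are eligible,
the patient enters the queue with the fewest waiting entities; ties resolve
by fixed declaration order (angioINR before angioIR), then entity id.  Note
that an idle-but-busy suite and an idle-and-free suite both count zero
waiting entities, so tie-breaks route to the first-declared suite — in the
baseline this concentrates elective IR work on the angioINR, which is
precisely the contention mechanism the scenarios probe.

Shift changes never preempt: when scheduled capacity drops below the
current busy count, running services complete and the pool simply admits no
new grants until the busy count falls below the new capacity.  Elective
procedure starts are gated to work hours (08:00–17:00): the bundle request
may queue at any time but may only be *granted* inside the window.  The
prep step (one unit from the staff pool) is not gated.

### Service durations

Per-case service durations were never logged, so they are calibration
inputs, not data: lognormal with coefficient of variation 0.5 and means of
15 min (ED triage), 20 (stroke assessment), 20 (CT), 30 (angio prep),
120 (ECR procedure), 120 (elective INR), 60 (emergency IR), 60 (elective
IR).  The means were chosen once so that baseline annual busy-minute
bookkeeping lands the angioINR occupancy in the mid-20s-to-low-30s percent
range; absolute wait-time magnitudes therefore carry no evidential weight,
and all scenario conclusions are stated directionally under common random
numbers.  Every duration is configurable (`fixed`, `exponential`,
`lognormal` with mean and cv).

### Scenarios

Scenario transforms are pure functions of the model (the baseline is a
fixed point): *exclusive* removes elective IR eligibility for the angioINR;
*two-inr* replaces the angioIR with a second angioINR open to all four
classes, staffing unchanged; *extended:H* (H ∈ {1, 2}) pushes the 17:00 day-
shift end of every staffed resource later by H hours and extends the
elective start gate identically (physical machines and 24 h pools are
untouched); *demand:K* multiplies demand.  The default demand mode
(`funnel`) scales P(suspected stroke | ED), so the suspected/AIS/ECR funnel
scales linearly while the raw ED volume and the elective/emergency IR
streams stay at their logged rates — this models growth in ECR demand
specifically, and keeps the comparison clean of an artificial ED-triage
bottleneck that scaling the raw ED stream would create.  Modes `all`
(every stream) and `ecr` (P(ECR | AIS) only) are available.  Whether the
elective gate should follow the extended shift is not empirically settled;
we extend it, since an extended day without elective access would idle the
very staff the scenario pays for.

### Outcome measures

*Wait time* is queue-entry to seizure, one sample per completed pair;
entities still queued or in service at the horizon are flagged incomplete
and excluded from wait statistics to avoid censoring bias (they remain in
the log).  *Utilization* is busy-unit-minutes divided by scheduled
capacity-minutes; the median across replications is the headline occupancy.
Because most patients never wait, cross-scenario comparison uses the
*standardized density*: the histogram density (default binwidth 1 min) of
positive waits divided by the count of zero-wait patients — the relative
probability of waiting a given time versus not waiting at all.  Waits
≤ 1e-9 min count as zero so that same-instant handoffs register as no wait.
A wait reduction converts to clinical benefit at 4.2 days of disability-free
life per minute, reported in days and in weeks rounded to the nearest half
week.  No significance testing is performed by design: with enough
replications any difference becomes "significant", so effect sizes and
directions are reported instead.

### Replication and randomness

The study conditions are 30 replications of a 365-day (525,600 min) year
per scenario, warm-up 0 (the year-long horizon makes initialization bias
negligible at these loads).  Replication *r* uses root seed XOR *r*; within
a replication every arrival source and every duration/branch sampler draws
from an independent named stream derived as `SeedSequence([seed,
crc32(name)])`.  Two arms run with the same root seed therefore share
arrival times and duration draws stream for stream (common random numbers),
which is how all scenario deltas are computed.  Identical configuration and
seed reproduce byte-identical event logs; event-calendar ties break by
insertion order and queue ties by (priority, enqueue order, declaration
order).

## Validation

The kernel is checked against two independent oracles (`ecr_des.validation`,
also exposed as `ecr-des validate`):

- **Closed forms**: simulated M/M/1 and M/M/2 mean queue waits must fall
  within 3 Monte-Carlo standard errors (across 12 replications of
  20,000 min, 2,000 min warm-up) of λ/(μ(μ−λ)) and the Erlang-C formula at
  ρ ∈ {0.3, 0.6, 0.9}.
- **Brute-force stepper**: a direct chronological single-server
  re-implementation of non-preemptive priority/FIFO service.  Engine waits
  must match it exactly on randomized integer-time instances (≤ 20
  entities, mixed priorities).  Integer times deliberately generate ties;
  the stepper encodes the engine's documented sequential-event tie
  semantics (an arrival finding an idle server starts immediately;
  same-instant arrivals at a busy server compete by priority).

## Numerical and degenerate-input choices

Time is real-valued minutes throughout.  Capacity schedules must tile
[0, 1440) exactly with integer capacities and repeat daily; lookups use a
per-minute table.  A rate-zero stream is a valid silent source.  Requests
for more units than a resource's scheduled maximum, references to unknown
resources, ineligible classes, and releases of unheld units all raise
typed errors rather than corrupting state.  The standardized density is
undefined when no patient had zero wait and raises with advice to fall back
to a raw histogram.  Event generation stops at the horizon; in-flight
services are censored there for utilization purposes (busy time accrues to
the horizon).

## What the defaults do and do not show

With shipped defaults the simulated service reproduces the qualitative
findings: the angioINR is the dominant bottleneck for ECR patients;
reserving it for emergency/INR work (exclusive) shortens ECR waits the most
while leaving the suite underutilized; a second angioINR helps less but
keeps the suite busy; extended hours help mainly in combination with
exclusive use; and doubling or tripling ECR demand lengthens waits on the
standardized scale without moving the bottleneck.  One second-order
behavior deserves a note: the *pooled mean* ECR wait can dip slightly at
2x demand before rising at 3x, because additional priority-0 stroke
traffic at the angioINR makes elective IR patients divert to the angioIR
at routing time, so an arriving ECR patient less often finds a long
elective case in progress; the standardized waiting mass and the suite
occupancy remain monotone in demand, which is why demand effects are
stated on that scale.  Because service durations are calibrated rather
than measured, the *magnitudes* of these effects (minutes saved, occupancy
percentages) are properties of the calibration, not of any real service;
passing tests demonstrate internal consistency and directional behavior,
not site-specific prediction.  Real arrival patterns (seasonality, time of
day, day of week) are not modelled — arrivals are homogeneous Poisson —
and no patient attributes beyond class, no inter-hospital transfers, and
no cost accounting are included.

## Problem sizes used in tests

Unit tests use scripted instances and short horizons (days, not years).
The acceptance suite and `scripts/acceptance.py` run the full study
conditions — 30 × 365 days — for seven arms (baseline, exclusive, two-inr,
extended:1 under baseline and exclusive, demand:2, demand:3), which the
package completes in minutes on one CPU; the extended:2 variants behave
like extended:1 and are exercised in the scenario unit tests.
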