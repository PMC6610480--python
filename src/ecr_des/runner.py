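"""Replication orchestration: run scenarios, aggregate metrics, compare runs.

A run simulates ``replications`` independent 365-day years of the service
under one scenario.  Replication ``r`` uses root seed XOR ``r``; two runs
with the same root seed therefore share arrival and duration streams arm
for arm (common random numbers), which is the recommended way to compare
scenarios.

Event logs are processed into wait samples and occupancy figures one
replication at a time, so memory stays flat; pass ``emit_event_log`` to
keep the per-replication CSV logs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .config import RunConfig
from .engine import ZERO_WAIT_TOLERANCE
from .errors import ConfigurationError
from .metrics import (
    DFLConfig,
    busy_minutes_by_resource,
    disability_free_life,
    standardized_density,
    wait_times,
)
from .model import ECRModel
from .scenarios import apply_scenario

__all__ = ["RunResult", "run_replications", "compare", "load_summary"]


@dataclass
class RunResult:
    """Aggregated outcomes of one scenario run."""

    scenario: str
    replications: int
    horizon_days: float
    warmup_days: float
    seed: int
    suite_names: tuple
    resource_names: tuple
    #: (patient_class, resource) -> list of per-replication wait arrays
    waits: dict = field(default_factory=dict)
    #: resource -> per-replication occupancy array
    utilization: dict = field(default_factory=dict)
    #: resource -> class -> share of busy-minutes
    class_attribution: dict = field(default_factory=dict)
    #: stream -> per-replication arrival counts
    stream_counts: dict = field(default_factory=dict)
    #: per-replication number of completed ECR procedures
    ecr_completed: list = field(default_factory=list)

    # -- views ---------------------------------------------------------

    def pooled_waits(self, patient_class: str, resource) -> np.ndarray:
        names = (resource,) if isinstance(resource, str) else tuple(resource)
        parts = []
        for name in names:
            for arr in self.waits.get((patient_class, name), []):
                parts.append(arr)
        return np.concatenate(parts) if parts else np.empty(0)

    def ecr_suite_waits(self) -> np.ndarray:
        """ECR (stroke-class) waits for the angiography suite bundle, all suites pooled."""
        return self.pooled_waits("stroke", self.suite_names)

    def mean_ecr_suite_wait(self) -> float:
        w = self.ecr_suite_waits()
        return float(w.mean()) if w.size else 0.0

    def median_utilization(self, resource: str) -> float:
        return float(np.median(self.utilization[resource]))

    def summary(self) -> dict:
        per_resource = {}
        for name in self.resource_names:
            util = self.utilization.get(name)
            if util is None:
                continue
            per_resource[name] = {
                "median_utilization": float(np.median(util)),
                "mean_utilization": float(np.mean(util)),
                "class_attribution": self.class_attribution.get(name, {}),
            }
        per_class: dict = {}
        for (cls, res), arrays in sorted(self.waits.items()):
            w = np.concatenate(arrays) if arrays else np.empty(0)
            entry = per_class.setdefault(cls, {})
            entry[res] = {
                "n": int(w.size),
                "mean_wait": float(w.mean()) if w.size else 0.0,
                "sd": float(w.std(ddof=1)) if w.size > 1 else 0.0,
                "zero_wait_fraction": float((w <= ZERO_WAIT_TOLERANCE).mean()) if w.size else 0.0,
            }
        return {
            "scenario": self.scenario,
            "replications": self.replications,
            "horizon_days": self.horizon_days,
            "warmup_days": self.warmup_days,
            "seed": self.seed,
            "suites": list(self.suite_names),
            "ecr_completed_mean": float(np.mean(self.ecr_completed)) if self.ecr_completed else 0.0,
            "mean_ecr_suite_wait": self.mean_ecr_suite_wait(),
            "stream_counts_mean": {
                k: float(np.mean(v)) for k, v in sorted(self.stream_counts.items())
            },
            "per_resource": per_resource,
            "per_class": per_class,
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        # standardized wait density of ECR patients at the suite bundle
        w = self.ecr_suite_waits()
        if w.size and (w <= ZERO_WAIT_TOLERANCE).any():
            standardized_density(w).to_csv(out / "density_ecr_angioinr.csv")


def run_replications(
    model: ECRModel,
    run_config: RunConfig,
    *,
    scenario: Optional[str] = None,
) -> RunResult:
    """Run all replications of one scenario and aggregate the outcome measures."""
    spec = scenario if scenario is not None else run_config.scenario
    scoped = apply_scenario(model, spec)
    horizon = run_config.horizon_min
    warmup = run_config.warmup_min
    suite_names = scoped.suite_names
    res_by_name = {r.name: r for r in scoped.resources}
    result = RunResult(
        scenario=spec,
        replications=run_config.replications,
        horizon_days=run_config.horizon_days,
        warmup_days=run_config.warmup_days,
        seed=run_config.seed,
        suite_names=suite_names,
        resource_names=tuple(res_by_name),
    )
    util_acc = {name: [] for name in res_by_name}
    attr_acc: dict = {name: {} for name in res_by_name}
    out_dir = Path(run_config.out_dir) if run_config.out_dir else None
    for r in range(run_config.replications):
        rep_seed = run_config.seed ^ r
        log = scoped.simulate(horizon, rep_seed, replication_id=r, scenario_name=spec)
        if run_config.emit_event_log and out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            log.to_csv(out_dir / f"events_rep{r:03d}.csv")
        df = wait_times(log, warmup=warmup)
        for (cls, res), grp in df.groupby(["patient_class", "resource"], sort=False):
            result.waits.setdefault((cls, res), []).append(grp["wait"].to_numpy())
        busy_by_res = busy_minutes_by_resource(log, warmup=warmup)
        for name, spec_r in res_by_name.items():
            cap = spec_r.schedule.capacity_minutes(warmup, horizon)
            busy, per_class = busy_by_res[name]
            util_acc[name].append(busy / cap if cap > 0 else 0.0)
            for cls, v in per_class.items():
                attr_acc[name][cls] = attr_acc[name].get(cls, 0.0) + v
        for stream, n in log.stream_counts.items():
            result.stream_counts.setdefault(stream, []).append(n)
        is_ecr = (df["patient_class"] == "stroke") & df["resource"].isin(suite_names)
        result.ecr_completed.append(int(is_ecr.sum()))
    for name in res_by_name:
        result.utilization[name] = np.asarray(util_acc[name])
        total = sum(attr_acc[name].values())
        result.class_attribution[name] = (
            {cls: v / total for cls, v in attr_acc[name].items()} if total > 0 else {}
        )
    if out_dir is not None:
        result.write(out_dir)
    return result


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

def _summary_of(run) -> dict:
    if isinstance(run, RunResult):
        return run.summary()
    if isinstance(run, dict):
        return run
    return load_summary(run)


def load_summary(run_dir) -> dict:
    path = Path(run_dir) / "summary.json"
    if not path.exists():
        raise ConfigurationError(f"no summary.json under {run_dir}")
    with open(path) as fh:
        return json.load(fh)


def compare(run_a, run_b, *, dfl: DFLConfig = DFLConfig()) -> dict:
    """Delta report of run A relative to baseline run B (positive = A waits less).

    Accepts :class:`RunResult` objects, summary dicts, or run directories
    containing ``summary.json``.  Requires matching horizon and replication
    counts so the arms are comparable.
    """
    a = _summary_of(run_a)
    b = _summary_of(run_b)
    for key in ("horizon_days", "replications"):
        if a[key] != b[key]:
            raise ConfigurationError(
                f"incompatible runs: {key} differs ({a[key]} vs {b[key]})"
            )
    wait_deltas: dict = {}
    for cls, resources in b.get("per_class", {}).items():
        for res, stats in resources.items():
            a_stats = a.get("per_class", {}).get(cls, {}).get(res)
            if a_stats is None:
                continue
            wait_deltas.setdefault(cls, {})[res] = stats["mean_wait"] - a_stats["mean_wait"]
    util_deltas = {}
    for res, stats in b.get("per_resource", {}).items():
        a_stats = a.get("per_resource", {}).get(res)
        if a_stats is not None:
            util_deltas[res] = (
                a_stats["median_utilization"] - stats["median_utilization"]
            )
    ecr_delta = b["mean_ecr_suite_wait"] - a["mean_ecr_suite_wait"]
    gain = disability_free_life(ecr_delta, dfl)
    return {
        "scenario": a["scenario"],
        "baseline": b["scenario"],
        "ecr_suite_wait_delta_min": ecr_delta,
        "dfl_days": gain.days,
        "dfl_weeks": gain.weeks,
        "dfl_weeks_rounded": gain.weeks_rounded,
        "wait_deltas_min": wait_deltas,
        "utilization_deltas": util_deltas,
    }
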