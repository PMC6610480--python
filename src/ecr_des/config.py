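"""Configuration loading and validation.

Parameters load from a YAML (or JSON) file with sections ``resources``,
``patients``, ``durations``, ``branching``, ``demand`` and ``run``.  Every
key is optional: unspecified values take the in-package defaults (the
service's logged annual counts, resource pools and shift schedules).
Validation reports every violated invariant with its key path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from .engine import CapacitySchedule, MINUTES_PER_DAY, ResourceSpec
from .errors import ConfigValidationError, ScheduleError
from .model import (
    DEFAULT_DURATIONS,
    DurationSpec,
    ECRModel,
    ModelParams,
    PATIENT_CLASSES,
    default_resources,
)

__all__ = ["RunConfig", "load_config", "parse_config", "default_config"]


@dataclass(frozen=True)
class RunConfig:
    """Replication orchestration settings."""

    scenario: str = "baseline"
    horizon_days: float = 365.0
    replications: int = 30
    seed: int = 0
    warmup_days: float = 0.0
    out_dir: Optional[str] = None
    emit_event_log: bool = False

    def __post_init__(self) -> None:
        problems = []
        if self.replications < 1:
            problems.append(f"run.replications: must be >= 1, got {self.replications}")
        if not (self.horizon_days > self.warmup_days >= 0):
            problems.append(
                f"run: need horizon_days > warmup_days >= 0, "
                f"got {self.horizon_days} and {self.warmup_days}"
            )
        if problems:
            raise ConfigValidationError(problems)

    @property
    def horizon_min(self) -> float:
        return self.horizon_days * MINUTES_PER_DAY

    @property
    def warmup_min(self) -> float:
        return self.warmup_days * MINUTES_PER_DAY


def _parse_clock(value, path: str, problems: list) -> Optional[float]:
    """\"08:00\" or minutes-of-day number -> minutes."""
    if isinstance(value, (int, float)):
        m = float(value)
    else:
        try:
            hh, mm = str(value).split(":")
            m = int(hh) * 60.0 + int(mm)
        except (ValueError, AttributeError):
            problems.append(f"{path}: cannot parse clock time {value!r}")
            return None
    if not (0 <= m <= MINUTES_PER_DAY):
        problems.append(f"{path}: {m} minutes outside [0, 1440]")
        return None
    return m


def _build_resource(name: str, spec: dict, base: Optional[ResourceSpec], problems: list):
    defaults = base
    day_cap = spec.get("day_capacity", spec.get("capacity"))
    night_cap = spec.get("night_capacity", day_cap)
    day_start = _parse_clock(spec.get("day_start", "08:00"), f"resources.{name}.day_start", problems)
    day_end = _parse_clock(spec.get("day_end", "17:00"), f"resources.{name}.day_end", problems)
    if day_cap is None and defaults is not None:
        schedule = defaults.schedule
    else:
        if day_cap is None:
            problems.append(f"resources.{name}: capacity required for a new resource")
            return None
        for label, cap in (("day_capacity", day_cap), ("night_capacity", night_cap)):
            if not isinstance(cap, int) or cap < 0:
                problems.append(f"resources.{name}.{label}: must be a non-negative integer, got {cap!r}")
                return None
        if day_start is None or day_end is None:
            return None
        try:
            schedule = CapacitySchedule.day_night(day_cap, night_cap, day_start, day_end)
        except ScheduleError as exc:
            problems.append(f"resources.{name}: {exc}")
            return None
    eligible = spec.get("eligible_classes")
    if eligible is None:
        if defaults is None:
            problems.append(f"resources.{name}.eligible_classes: required for a new resource")
            return None
        eligible = defaults.eligible_classes
    else:
        bad = [c for c in eligible if c not in PATIENT_CLASSES]
        if bad:
            problems.append(f"resources.{name}.eligible_classes: unknown classes {bad}")
            return None
        if not eligible:
            problems.append(f"resources.{name}.eligible_classes: must be non-empty")
            return None
    kind = spec.get("kind", defaults.kind if defaults else "other")
    human = bool(spec.get("human", defaults.human if defaults else False))
    return ResourceSpec(name, schedule, frozenset(eligible), kind=kind, human=human)


def _build_durations(section: dict, problems: list) -> dict:
    durations = dict(DEFAULT_DURATIONS)
    for key, spec in section.items():
        if not isinstance(spec, dict):
            spec = {"mean": spec}
        dist = spec.get("distribution", "lognormal")
        mean = spec.get("mean")
        cv = spec.get("cv", 0.5)
        if mean is None:
            problems.append(f"durations.{key}.mean: required")
            continue
        try:
            durations[key] = DurationSpec(dist, float(mean), float(cv))
        except Exception as exc:
            problems.append(f"durations.{key}: {exc}")
    return durations


def parse_config(data: Optional[dict]) -> tuple[ECRModel, RunConfig]:
    """Build a validated model and run configuration from a config mapping."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigValidationError(["top level: expected a mapping"])
    problems: list[str] = []
    known_sections = {"resources", "patients", "durations", "branching", "demand", "run"}
    for key in data:
        if key not in known_sections:
            import warnings

            warnings.warn(f"config: unknown section '{key}' ignored", stacklevel=2)

    # resources --------------------------------------------------------
    base = {r.name: r for r in default_resources()}
    order = list(base)
    resources_cfg = data.get("resources", {}) or {}
    for name, spec in resources_cfg.items():
        built = _build_resource(name, spec or {}, base.get(name), problems)
        if built is not None:
            if name not in base:
                order.append(name)
            base[name] = built
    resources = [base[n] for n in order]

    # patients ---------------------------------------------------------
    patients = data.get("patients", {}) or {}
    annual = dict(ModelParams().annual_counts)
    for key, n in (patients.get("annual_counts", {}) or {}).items():
        if key not in annual:
            problems.append(f"patients.annual_counts.{key}: unknown patient stream")
        elif not isinstance(n, (int, float)) or n < 0:
            problems.append(f"patients.annual_counts.{key}: must be a non-negative number, got {n!r}")
        else:
            annual[key] = n
    overrides = {}
    for key, ia in (patients.get("interarrival_min", {}) or {}).items():
        if ia is not None and (not isinstance(ia, (int, float)) or ia < 0):
            problems.append(f"patients.interarrival_min.{key}: must be non-negative, got {ia!r}")
        else:
            overrides[key] = ia

    # durations / branching / demand ------------------------------------
    durations = _build_durations(data.get("durations", {}) or {}, problems)
    branching = dict(data.get("branching", {}) or {})
    demand = data.get("demand", {}) or {}

    run_cfg_section = data.get("run", {}) or {}
    if problems:
        raise ConfigValidationError(problems)

    try:
        params = ModelParams(
            annual_counts=annual,
            interarrival_overrides=overrides,
            branch_overrides=branching,
            durations=durations,
            demand_multiplier=float(demand.get("multiplier", 1.0)),
            demand_mode=demand.get("mode", "funnel"),
            background_ed=bool(patients.get("background_ed", True)),
            independent_streams=bool(patients.get("independent_streams", False)),
        )
    except ConfigValidationError:
        raise
    run_cfg = RunConfig(
        scenario=str(run_cfg_section.get("scenario", "baseline")),
        horizon_days=float(run_cfg_section.get("horizon_days", 365)),
        replications=int(run_cfg_section.get("replications", 30)),
        seed=int(run_cfg_section.get("seed", 0)),
        warmup_days=float(run_cfg_section.get("warmup_days", 0)),
        out_dir=run_cfg_section.get("out"),
        emit_event_log=bool(run_cfg_section.get("emit_event_log", False)),
    )
    return ECRModel(params=params, resources=tuple(resources)), run_cfg


def load_config(path) -> tuple[ECRModel, RunConfig]:
    """Load and validate a YAML/JSON config file; empty file -> full defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigValidationError([f"parse error in {path}: {exc}"]) from exc
    return parse_config(data)


def default_config() -> tuple[ECRModel, RunConfig]:
    return parse_config({})
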