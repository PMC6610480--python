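"""Exception hierarchy for the ECR service simulator."""


class ECRDESError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ECRDESError):
    """A model definition references something that does not exist or is malformed."""


class ConfigValidationError(ConfigurationError):
    """One or more config invariants violated; carries the offending key paths."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in self.problems))


class ScheduleError(ECRDESError):
    """A capacity schedule does not tile the day or has invalid capacities."""


class EligibilityError(ECRDESError):
    """An entity requested a resource its patient class may not use."""


class ConsistencyError(ECRDESError):
    """Internal bookkeeping violated (e.g. releasing units that are not held)."""


class RoutingError(ECRDESError):
    """No eligible resource candidate for a routing decision."""


class FilterError(ECRDESError):
    """A metrics filter referenced an unknown resource or patient class."""


class NormalizationError(ECRDESError):
    """Standardized density undefined because no patient had zero wait."""
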