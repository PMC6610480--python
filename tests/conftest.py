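import pytest

from ecr_des import ECRModel
from ecr_des.engine import CapacitySchedule, Engine, ResourceSpec


@pytest.fixture
def default_model():
    return ECRModel.default()


@pytest.fixture
def single_server():
    """A one-unit constant-capacity resource accepting class 'job'."""
    return ResourceSpec("server", CapacitySchedule.constant(1), frozenset({"job"}))


def make_engine(resources, horizon=10_000.0, **kw):
    return Engine(resources, horizon, **kw)


def job_factory(service, needs=None, priority=0, gated=False):
    """Simple seize -> serve -> release process for engine-level tests."""
    needs = needs or {"server": 1}

    def factory(_entity):
        yield ("seize", dict(needs), priority, gated)
        yield ("timeout", service)
        yield ("release", dict(needs))

    return factory
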