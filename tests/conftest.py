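import functools

import pytest

from neocirc.model_core import load_preset
from neocirc.scenarios import get_scenario, registry, run_scenario


@pytest.fixture(scope="session")
def preterm():
    return load_preset("preterm")


@pytest.fixture(scope="session")
def adult():
    return load_preset("adult")


@functools.lru_cache(maxsize=None)
def _cached_run(name: str, rtol: float = 1e-8, atol: float = 1e-10):
    return run_scenario(name, rtol=rtol, atol=atol)


@pytest.fixture(scope="session")
def scenario_run():
    """Memoized scenario runner shared across the whole session."""
    return _cached_run


@pytest.fixture(scope="session")
def all_scenario_names():
    return [sc.name for sc in registry()]


@pytest.fixture(scope="session")
def roche_template():
    return get_scenario("roche_labarbe")
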