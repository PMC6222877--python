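import numpy as np
import pytest

from tunnelflex import fixtures, pipeline


@pytest.fixture(scope="session")
def worked_graph():
    return fixtures.worked_example_graph()


@pytest.fixture(scope="session")
def worked_geometry():
    return fixtures.worked_example_geometry()


@pytest.fixture(scope="session")
def worked_pipeline(worked_geometry):
    molecule, tunnel = worked_geometry
    return pipeline.enumerate_conformations(
        molecule, tunnel, step=fixtures.WORKED_EXAMPLE_STEP
    )


@pytest.fixture(scope="session")
def toy_cache():
    """Memoized toys so several test modules can share the generation cost."""
    cache = {}

    def get(**kwargs):
        key = tuple(sorted(kwargs.items()))
        if key not in cache:
            spec = fixtures.ToySpec(**kwargs)
            cache[key] = (spec, *fixtures.random_toy(spec))
        return cache[key]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
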