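import pytest

from pigcre import pipeline
from pigcre.synthetic import simulate_study


@pytest.fixture(scope="session")
def study():
    """The default synthetic study under a fixed seed."""
    return simulate_study(seed=1)


@pytest.fixture(scope="session")
def catalogue(study):
    return pipeline.call_catalogue(study)


@pytest.fixture(scope="session")
def tad_calls(study):
    return pipeline.call_tads(study)
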