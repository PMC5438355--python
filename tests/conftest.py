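import pytest
from hypothesis import settings

from flowattrib import GeneratorParams, PeriodDefinition, generate_catchment

settings.register_profile("default", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def periods():
    return PeriodDefinition()


@pytest.fixture(scope="session")
def default_run():
    """One default two-era synthetic catchment (18+13 years) with truth."""
    return generate_catchment(GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def noisefree_run():
    """Noise-free variant: exact Budyko ET and closed water balance."""
    params = GeneratorParams(seed=11, sigma_ET_noise=0.0, sigma_S=0.0)
    return generate_catchment(params)
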