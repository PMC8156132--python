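import pytest
from hypothesis import settings

from proreq.simulate import SyntheticConfig, default_diets, generate_trial

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def trial():
    """One synthetic 16-animal, 2-period trial under the default conditions."""
    return generate_trial(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def diets():
    return default_diets()


@pytest.fixture()
def diet_low(diets):
    """The lowest-CP (5.4% DM) diet."""
    return diets[0]
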