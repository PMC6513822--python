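import pytest
from hypothesis import HealthCheck, settings

from spendsim import ExpenditureMicrosimulation
from spendsim.synthetic_data import generate_world

settings.register_profile(
    "fixed",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def tiny_world():
    """Small world: 5 zones, ~400 adults each, 900-person survey."""
    return generate_world(
        n_zones=5, mean_adults=400, mean_children=100, survey_size=900, seed=3
    )


@pytest.fixture(scope="session")
def tiny_results(tiny_world):
    return ExpenditureMicrosimulation.from_world(tiny_world).fit()


@pytest.fixture(scope="session")
def study_world():
    """Study-scale world: 30 zones, ~2500 adults per zone, 6000 survey
    individuals — the conditions the validation checks assume."""
    return generate_world(seed=1)


@pytest.fixture(scope="session")
def study_results(study_world):
    return ExpenditureMicrosimulation.from_world(study_world).fit()
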