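import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from retinagaze import CohortConfig, generate_layout, simulate_cohort
from retinagaze.aoi import expand_annotation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    annotation, geometry = generate_layout(seed=1)
    return annotation, geometry


@pytest.fixture(scope="session")
def expanded(layout):
    annotation, _ = layout
    return expand_annotation(annotation)


@pytest.fixture(scope="session")
def small_bundle():
    """A 4-grader x 5-image cohort, enough for end-to-end checks."""
    return simulate_cohort(CohortConfig(n_participants=4, n_images=5, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
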