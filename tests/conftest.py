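import pytest

from fhiromop.forward_transform import TransformContext
from fhiromop.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def ctx() -> TransformContext:
    """Transform context with the shipped concept maps (fresh warning sink per use
    is not needed at session scope: tests that assert on warnings build their own)."""
    return TransformContext.default()


@pytest.fixture(scope="session")
def cohort():
    """Default deterministic cohort: 5 patients x 4 observations, all nine
    vital-sign types represented."""
    return generate_cohort(CohortConfig(seed=42))


@pytest.fixture()
def fresh_ctx() -> TransformContext:
    return TransformContext.default()
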