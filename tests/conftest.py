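import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def motility_samples():
    """Small deterministic paired motility dataset (18 males)."""
    from spermcomp import generate_motility
    from spermcomp.config import MotilityGenConfig

    return generate_motility(MotilityGenConfig(), seed=42)


@pytest.fixture
def fertilisation_trials():
    """Deterministic reciprocal-cross trials, null dye effect."""
    from spermcomp import generate_fertilisation
    from spermcomp.config import FertilisationGenConfig

    return generate_fertilisation(FertilisationGenConfig(), seed=42)
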