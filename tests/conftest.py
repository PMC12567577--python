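import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-participant cohort at study defaults (shared, read-only)."""
    from tremorband.synthetic import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=11, n_participants=6))


@pytest.fixture(scope="session")
def small_indices(small_cohort):
    from tremorband.pipeline import run_extract

    return run_extract(trials=small_cohort.trials)
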