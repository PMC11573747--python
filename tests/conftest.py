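import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def simple_population():
    from scenith import PopulationSpec

    return PopulationSpec(
        name="mac", n_events=2000, g=75.0, m=25.0, marker_means={"lineage": 1e3}
    )


@pytest.fixture()
def pooled_sim(simple_population):
    """A small pooled single-sample simulation with default noise."""
    from scenith import SimulationSpec, simulate_experiment

    spec = SimulationSpec.single([simple_population], seed=7)
    return simulate_experiment(spec)
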