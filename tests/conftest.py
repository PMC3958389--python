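import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def strong_qtl_pop():
    """A reciprocal F2 population with a strong QTL (estimation-study preset)."""
    from cytoqtl.simulate import simulate_population, table2_scenario

    scen = table2_scenario(h2=0.4, n=400, seed=12345)
    return simulate_population(scen), scen.genetic_map(), scen


@pytest.fixture(scope="session")
def null_pop():
    """A population with no genetic effects at all (pure noise + mean)."""
    from cytoqtl.design import EffectVector
    from cytoqtl.simulate import SimulationScenario, simulate_population

    scen = SimulationScenario(
        n=300, beta=EffectVector(mu=10.0), sigma2=1.0, seed=999
    )
    return simulate_population(scen), scen.genetic_map(), scen


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
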