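import numpy as np
import pytest

import trimorph as tm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def payoff():
    return tm.PayoffMatrix.default()


@pytest.fixture
def small_config():
    """Fast default scenario: short-lived life cycle at K=500."""
    return tm.ScenarioConfig(
        mechanism=tm.GeneticMechanism(mode="dominance", heterozygote_cost=0.0),
        lifecycle=tm.LifeCycleParams.short_lived(K=500),
        T=50,
        seed=3,
    )


@pytest.fixture
def two_male_population():
    """One polygynous male holding females, one monogamous rival."""
    spec = tm.MiniPopulationSpec(
        members=(
            (1, "male", "adult", "pp", "P"),
            (1, "male", "adult", "mm", "M"),
            (3, "female", "adult", "mm", None),
        )
    )
    return tm.make_population(spec)
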