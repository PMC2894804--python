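import numpy as np
import pytest

from oxiswitch.synthetic_data import (
    SimulationConfig,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def small_experiment():
    """A 400-gene default-noise experiment shared across test modules."""
    cfg = SimulationConfig(n_probesets=400, seed=5)
    layout, truth, pim = simulate_experiment(cfg)
    return cfg, layout, truth, pim


@pytest.fixture(scope="session")
def small_summaries(small_experiment):
    from oxiswitch.probe_summarization import summarize_all

    _, _, _, pim = small_experiment
    return summarize_all(pim)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
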