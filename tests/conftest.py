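import pytest
from hypothesis import settings

import haloseq as h

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return h.SimulationConfig(n_genes=40, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small simulated experiment shared across read-only tests."""
    return h.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def sense_models(small_dataset):
    return [m for m in small_dataset["annotation"] if m.gene_class != "uaRNA"]
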