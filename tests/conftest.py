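import numpy as np
import pytest

from clipsplice.pipeline import PipelineInputs, run_pipeline
from clipsplice.simulate import SimulationConfig, simulate_dataset


def tiny_config(**overrides) -> SimulationConfig:
    """A fast, fully featured configuration for unit tests."""
    params = dict(
        n_genes=20,
        n_cassette_events=20,
        n_direct_repressed=4,
        n_direct_activated=2,
        n_bound_unresponsive=2,
        n_responsive_unbound=2,
        n_binding_sites=10,
        n_induced_strong=3,
        n_induced_weak=2,
        n_repressed_expression=1,
        n_chip_decoys=3,
        seed=7,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@pytest.fixture(scope="session")
def default_dataset():
    """The default-scale synthetic dataset (the study conditions)."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline run on the default synthetic dataset."""
    return run_pipeline(inputs=PipelineInputs.from_dataset(default_dataset), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
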