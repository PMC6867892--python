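import pytest

from rotstage.pipeline import run_pipeline
from rotstage.synthdata import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    """Moderate synthetic experiment reused across recovery tests."""
    return SimulationConfig(n_orthogroups=500, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Full pipeline result on the shared small dataset."""
    return run_pipeline(dataset=small_dataset)


@pytest.fixture(scope="session")
def study_run():
    """Pipeline result at the default study conditions (full catalog size);
    shared because the statistical pattern properties are only powered at
    this scale."""
    return run_pipeline(config=SimulationConfig(seed=20))
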