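import numpy as np
import pytest

from tumorconn.synthetic import SimulationConfig, generate_connectome_cohort


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A miniature study: 36 active nodes, 8 DMN regions, short series."""
    return SimulationConfig(
        seed=11,
        n_controls=5,
        n_patients=6,
        n_regions_dmn=8,
        n_volumes=64,
        n_atlas_labels=40,
        n_empty_labels=4,
        tumor_volume_voxels=60,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_connectome_cohort(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
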