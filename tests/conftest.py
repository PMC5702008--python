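import pytest

from rhizoscreen.datasets import load_study_genome_summary
from rhizoscreen.simulate import SimConfig, generate_dataset

#: Small 7-strain scenario used by unit tests (exact-DP engine friendly).
TINY = SimConfig(
    n_per_group=(2, 2, 2),
    n_families=30,
    island_size=5,
    family_length_range=(60, 80),
    n_scaffolds=3,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    return TINY


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(TINY)


@pytest.fixture(scope="session")
def study_summary():
    """Published genome summary table of the 23-strain study."""
    return load_study_genome_summary()
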