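import pytest

from cytoscan.genome import GenomeAnnotation, MajorBand
from cytoscan.simulate import SimulationConfig, make_genome


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Single chromosome, two adjacent bands of 1 Mb each plus one on chr2."""
    return GenomeAnnotation(
        [
            MajorBand("1p11", "1", 0, 1_000_000),
            MajorBand("1q11", "1", 1_000_000, 2_000_000),
            MajorBand("2q11", "2", 0, 3_000_000),
        ]
    )


@pytest.fixture(scope="session")
def default_genome() -> GenomeAnnotation:
    """The 23 x 14 = 322-band synthetic genome, seed 1."""
    return make_genome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)
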