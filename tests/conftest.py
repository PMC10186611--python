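import pytest

from subtelo.genome import GenomeAssembly
from subtelo.simulate import DEGSimConfig, SimulationConfig, generate_genome


@pytest.fixture
def toy_assembly():
    return GenomeAssembly(
        chromosomes=(("chr1", 10_000_000),),
        centromeres={"chr1": (4_000_000, 5_000_000)},
    )


@pytest.fixture(scope="session")
def small_config():
    """A quick-to-simulate genome for unit tests."""
    return SimulationConfig(
        seed=5,
        chromosome_lengths=(20_000_000, 16_000_000, 12_000_000),
        n_genes=2_000,
        deg=DEGSimConfig(n_degs=150, planted_fold=3.0),
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_genome(default_config):
    return generate_genome(default_config)
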