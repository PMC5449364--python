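import numpy as np
import pytest

from lectinkit.models import GeneModel
from lectinkit.simulate import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def small_config():
    """Compact study configuration used where genome scale is irrelevant."""
    return SimulationConfig(
        seed=11, n_chromosomes=2, genes_per_chromosome=30,
        tandem_array_spec=(("EUL", 3, "chr2"),),
        scattered_spec=(("EUL", 1), ("GNA", 2)),
        n_background_genes=60,
        module_spec=(("M1", 10, 8.0,
                      (("drought", 4.0), ("osmotic", 3.0), ("ABA", 2.0), ("JA", 0.5)),
                      0.35),),
    )


@pytest.fixture(scope="session")
def genome_sim(small_config):
    return simulate_genome(small_config)


@pytest.fixture
def plus_gene():
    """Two-exon plus-strand gene with UTRs flanking the CDS."""
    return GeneModel("gplus", "chr1", "+",
                     exons=((100, 200), (300, 450)),
                     cds=((130, 200), (300, 420)))


@pytest.fixture
def minus_gene():
    return GeneModel("gminus", "chr1", "-",
                     exons=((100, 200), (300, 450)),
                     cds=((130, 200), (300, 420)))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
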