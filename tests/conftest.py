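import pytest

from mutfrag import DesignSettings, DesignView, compute_codon_usage
from mutfrag.simulate import random_gene


@pytest.fixture
def settings():
    return DesignSettings()


@pytest.fixture
def toy_table():
    # codons: ATG GCA GCA GCG GAA TAA -> Ala {GCA: 2/3, GCG: 1/3}
    return compute_codon_usage(["ATGGCAGCAGCGGAATAA"], "toy")


@pytest.fixture
def small_gene():
    """A 200-codon random gene on a 2.6 kb circular plasmid."""
    plasmid, gene = random_gene(200, seed=11)
    return plasmid, gene


@pytest.fixture
def small_view(small_gene):
    plasmid, gene = small_gene
    return DesignView.build(plasmid, gene)
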