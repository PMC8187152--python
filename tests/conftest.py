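import numpy as np
import pytest

from devsplice.evolution import SpeciesTree
from devsplice.segments import GeneModel


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tree():
    return SpeciesTree()


@pytest.fixture
def cassette_gene():
    """3-exon gene; transcripts include/skip the middle exon."""
    return GeneModel(
        gene_id="g",
        chrom="chr1",
        strand="+",
        transcripts=[
            [(0, 100), (200, 300), (400, 500)],
            [(0, 100), (400, 500)],
        ],
    )


@pytest.fixture
def retention_gene():
    """2-exon gene; one transcript retains the intron."""
    return GeneModel(
        gene_id="g",
        chrom="chr1",
        strand="+",
        transcripts=[[(0, 100), (200, 300)], [(0, 300)]],
    )
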