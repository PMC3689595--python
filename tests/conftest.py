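import numpy as np
import pytest

from genoverlap.annotation_io import GeneRecord
from genoverlap.synthetic_data import GenomeSimParams, generate_genome


def make_gene(gene_id, start, end, seq_id="chr1", strand="+", exons=None, species="sp"):
    return GeneRecord(
        gene_id=gene_id, seq_id=seq_id, start=start, end=end, strand=strand,
        exons=tuple(exons) if exons else ((start, end),), species=species,
    )


@pytest.fixture
def small_genome():
    genes, truth = generate_genome(
        GenomeSimParams(n_genes=200, frac_overlapping=0.2, n_clusters=1, seed=11)
    )
    return genes, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
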