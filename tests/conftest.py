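import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from congener import synthdata as sd
from congener._seq import decode
from congener.core_io import SeqRecord


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_genome():
    """A 60 kb two-chromosome random genome used by several fixtures."""
    cfg = sd.SimConfig(genome_length=60_000, n_chromosomes=2, seed=101)
    return sd.simulate_reference(cfg)


@pytest.fixture()
def random_seq():
    def make(n, seed=0):
        r = np.random.default_rng(seed)
        return decode(r.integers(0, 4, size=n).astype(np.uint8))

    return make


@pytest.fixture()
def toy_gene_genome(random_seq):
    """A 4 kb chromosome carrying one two-exon protein-coding gene.

    Gene on the + strand: exon1 [1000,1100) with CDS [1040,1100),
    intron [1100,1300), exon2 [1300,1500) with CDS [1300,1402),
    so the CDS is 162 bp = 54 codons.  The first codon is forced to ATG
    and the last to TAA so start/stop logic is exercised.
    """
    from congener.core_io import GeneModel

    seq = list(random_seq(4000, seed=7))
    seq[1040:1043] = "ATG"
    seq[1399:1402] = "TAA"
    # keep internal codons stop-free so the oracle stays simple
    genome = [SeqRecord("chr1", "".join(seq), tier="chromosome")]
    model = GeneModel(
        gene_id="g1",
        transcript_id="t1",
        chrom="chr1",
        strand="+",
        exons=[(1000, 1100), (1300, 1500)],
        cds=[(1040, 1100), (1300, 1402)],
    )
    return genome, model
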