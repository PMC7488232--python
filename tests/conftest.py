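import pytest

from spotmap import GenomeSimConfig, make_genome_pair


@pytest.fixture(scope="session")
def genome_pair():
    """A small two-contig genome pair with planted RFLP variants and genes."""
    cfg = GenomeSimConfig(
        n_contigs=2,
        contig_length=60_000,
        n_planted_rflp=10,
        n_genes=8,
        seed=11,
    )
    return make_genome_pair(cfg)
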