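import pytest

from epimark.core import GeneModel, GenomicInterval
from epimark.synthetic import SyntheticConfig, generate_world, write_world


def make_gene(gene_id, chrom, start, end, strand="+", exons=None):
    iv = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exons = [(start, end)]
    return GeneModel(gene_id, iv, [GenomicInterval(chrom, s, e, strand) for s, e in exons])


@pytest.fixture(scope="session")
def world():
    """Default synthetic world shared by read-only tests."""
    return generate_world(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def world_dir(world, tmp_path_factory):
    d = tmp_path_factory.mktemp("world")
    paths = write_world(world, str(d))
    return paths
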