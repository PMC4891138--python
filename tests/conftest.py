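import pytest

from qualu import MiniGenomeSpec, default_scheme, find_sites, make_minigenome


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def mini_genome():
    """Mid-size planted mini-genome shared by oracle tests (seed fixed)."""
    spec = MiniGenomeSpec(
        n_alu=50, n_line=5, n_cgi=3, contig_length=40_000,
        alu_divergence_range=(0.0, 0.3), seed=7,
    )
    genome, annotations = make_minigenome(spec)
    return spec, genome, annotations


@pytest.fixture(scope="session")
def mini_sites(mini_genome):
    _, genome, _ = mini_genome
    return find_sites(genome)
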