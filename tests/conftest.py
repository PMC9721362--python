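import pytest

from emsomics import PipelineConfig, SimConfig
from emsomics import simulate as sim


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact two-chromosome dataset exercising every variant/region class."""
    return SimConfig(
        seed=7,
        n_chromosomes=2,
        chrom_length=200_000,
        n_genes=16,
        snp_rate=1.5e-3,
        indel_rate=2e-4,
        n_de_genes=4,
        n_dmrs=2,
        control_seq_length=10_000,
    )


@pytest.fixture(scope="session")
def genome_and_genes(small_cfg):
    return sim.simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def variant_data(small_cfg, genome_and_genes):
    genome, genes = genome_and_genes
    return sim.simulate_variants(genome, genes, small_cfg)


@pytest.fixture(scope="session")
def methylome_data(small_cfg, genome_and_genes):
    genome, _ = genome_and_genes
    return sim.simulate_methylome(genome, small_cfg)


@pytest.fixture()
def pipe_cfg() -> PipelineConfig:
    return PipelineConfig()
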