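import pytest
from hypothesis import settings

from cysvarforge.simulate import SimConfig, make_toy_genome_and_models

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def toy(sim_config):
    """Session-wide toy genome/models/proteome triple (seed 1)."""
    return make_toy_genome_and_models(sim_config)


@pytest.fixture(scope="session")
def toy_files(toy, tmp_path_factory):
    """The toy triple written to disk as FASTA/GTF."""
    from cysvarforge.simulate import (
        write_genome_fasta,
        write_gtf,
        write_proteome_fasta,
    )

    d = tmp_path_factory.mktemp("toy")
    write_genome_fasta(toy.genome, d / "genome.fa")
    write_gtf(toy.models, d / "models.gtf")
    write_proteome_fasta(toy.proteome, d / "proteome.fa")
    return d
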