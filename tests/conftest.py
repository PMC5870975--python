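import pytest

from mitocomp import synthetic_data as sd


@pytest.fixture(scope="session")
def config():
    return sd.GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def genome_and_truth(config):
    return sd.generate_mitogenome(config)


@pytest.fixture(scope="session")
def genome(genome_and_truth):
    return genome_and_truth[0]


@pytest.fixture(scope="session")
def truth(genome_and_truth):
    return genome_and_truth[1]


@pytest.fixture(scope="session")
def cohort(config):
    """Three full-size genomes for cross-genome stages."""
    return [sd.generate_mitogenome(config.with_seed(s))[0]
            for s in (11, 12, 13)]


@pytest.fixture(scope="session")
def ortholog_sets(config):
    return sd.generate_ortholog_trnas(config)
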