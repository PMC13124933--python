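import pytest
from hypothesis import settings

from agenet.mapping import map_snps_to_genes
from agenet.synthetic import StudyConfig, generate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


SMALL_CONFIG = StudyConfig(n_genes=300, n_ards=16, n_arcs=8, snps_per_ard=5,
                           planted_ageing_size=20, planted_pleio_size=20, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (the conditions the analyses target)."""
    return generate_study(StudyConfig())


@pytest.fixture(scope="session")
def default_assoc(default_study):
    s = default_study
    return map_snps_to_genes(s.snp_table, s.gene_ranges, arc_map=s.arc_map)


@pytest.fixture(scope="session")
def small_study():
    return generate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_assoc(small_study):
    s = small_study
    return map_snps_to_genes(s.snp_table, s.gene_ranges, arc_map=s.arc_map)
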