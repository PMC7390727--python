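import pytest

from pentacensus import annotate_receptors, io_tables
from pentacensus.simulate import generate, make_study_config


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A modest synthetic bundle (~150 genomes) shared across module tests."""
    out = tmp_path_factory.mktemp("bundle")
    bundle, truth = generate(make_study_config(150), out, seed=7)
    return bundle, truth


@pytest.fixture(scope="session")
def small_annotations(small_bundle):
    """Classified receptors of the small bundle, plus the loaded inputs."""
    bundle, truth = small_bundle
    records = io_tables.read_fasta(bundle.fasta)
    hits = io_tables.read_domain_table(bundle.domains)
    tm = io_tables.read_tm_table(bundle.tm)
    annotations = annotate_receptors(records, hits, tm)
    metadata = io_tables.read_proteome_metadata(bundle.metadata)
    habitat = io_tables.read_habitat_table(bundle.habitat)
    return annotations, metadata, habitat, truth
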