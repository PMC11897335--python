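import pytest

from mitochar.annotation import build_annotation_table
from mitochar.datasets import (
    load_published_annotation,
    load_published_values,
    published_genome_length,
)
from mitochar.simulate import generate_mitogenome, mutate_assembly


@pytest.fixture(scope="session")
def cat07_features():
    return load_published_annotation("cat07")


@pytest.fixture(scope="session")
def cat08_features():
    return load_published_annotation("cat08")


@pytest.fixture(scope="session")
def cat07_table(cat07_features):
    return build_annotation_table(cat07_features,
                                  genome_length=published_genome_length("cat07"),
                                  genome_id="cat07")


@pytest.fixture(scope="session")
def cat08_table(cat08_features):
    return build_annotation_table(cat08_features,
                                  genome_length=published_genome_length("cat08"),
                                  genome_id="cat08")


@pytest.fixture(scope="session")
def published_values():
    return load_published_values()


@pytest.fixture(scope="session")
def synth_truth():
    """The default synthetic genome (published layout, seed 42)."""
    return generate_mitogenome(seed=42)


@pytest.fixture(scope="session")
def synth_pair(synth_truth):
    """(truth, sister assembly, planted variants) with the default spectrum."""
    sister, variants = mutate_assembly(synth_truth, seed=7)
    return synth_truth, sister, variants
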