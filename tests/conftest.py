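import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from nanomon.reads import ReadRecord
from nanomon.taxonomy import TaxonNode, Taxonomy


@pytest.fixture
def toy_tree() -> Taxonomy:
    """root -> (g1 -> {s1, s2}, g2 -> {s3}); 6 nodes."""
    return Taxonomy(
        [
            TaxonNode(1, 1, "domain", "root"),
            TaxonNode(10, 1, "genus", "g1"),
            TaxonNode(20, 1, "genus", "g2"),
            TaxonNode(11, 10, "species", "s1"),
            TaxonNode(12, 10, "species", "s2"),
            TaxonNode(21, 20, "species", "s3"),
        ]
    )


def make_read(read_id: str, length: int, quality: int = 20, base: str = "A") -> ReadRecord:
    return ReadRecord(read_id, base * length, tuple([quality] * length))


@pytest.fixture
def read_factory():
    return make_read
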