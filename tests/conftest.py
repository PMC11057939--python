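import pytest

from snvfeat import fixtures
from snvfeat.core import VariantRecord
from snvfeat.sequence import ReferenceGenome


@pytest.fixture
def toy_genome():
    # fixed 60 bp contig: deterministic, hand-checkable
    return ReferenceGenome({"chr1": "AACGTTACGTGCGCATATCGCGTACGTAGCTAGCTAGGCCGGCCTTAACGCGTATATCCG"})


@pytest.fixture
def toy_variant(toy_genome):
    # position 10 of the toy contig is 'G'
    return VariantRecord("chr1", 10, 11, "G", "A")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full synthetic input bundle shared by integration tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = fixtures.FixtureConfig(seed=7)
    return fixtures.make_annotation_bundle(cfg, outdir)
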