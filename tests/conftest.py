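import pytest

from pedscreen.io import variants_from_table
from pedscreen.simulate import build_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """The deterministic study fixture: (pedigree, genotypes, annotations, SV table)."""
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_variants(paper_fixture):
    """Annotated variants of the fixture, in genotype-matrix order."""
    _ped, _geno, annotations, _sv = paper_fixture
    return variants_from_table(annotations)
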