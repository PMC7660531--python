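import pytest

from hemotyper.align import GeneIndex
from hemotyper.bundled import bundled_database


@pytest.fixture(scope="session")
def db():
    return bundled_database()


@pytest.fixture(scope="session")
def gene_index(db):
    return GeneIndex(db)
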