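import pytest

from molopt.corpus import build_records
from molopt.fixtures import FixtureSpec, generate_corpus
from molopt.props import SurrogateOracle


@pytest.fixture(scope="session")
def oracle():
    return SurrogateOracle()


@pytest.fixture(scope="session")
def small_corpus():
    """4 scaffolds x 6 R-groups: 24 molecules, 120 pairs."""
    return generate_corpus(FixtureSpec(n_scaffolds=4, r_library_size=6))


@pytest.fixture(scope="session")
def small_records(small_corpus, oracle):
    return build_records(small_corpus.pairs, oracle)


@pytest.fixture(scope="session")
def default_corpus():
    """The full default fixture library (8 scaffolds x 25 R-groups)."""
    return generate_corpus(FixtureSpec())
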