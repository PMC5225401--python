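import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

from mipassage.embeddings import AmbiguousRemovals
from mipassage.fixtures import (
    FixtureSpec,
    ToyEmbeddingSpec,
    generate_collection,
    generate_embeddings,
    toy_lexicon,
)
from mipassage.queries import build_baseline_queries, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return toy_lexicon()


@pytest.fixture(scope="session")
def psimi_lexicon():
    return default_lexicon()


@pytest.fixture()
def fixture_pair(lexicon):
    """Default (gold, bare) collection pair with name-variant plantings."""
    return generate_collection(FixtureSpec(), lexicon)


@pytest.fixture()
def baseline_table(lexicon):
    return build_baseline_queries(lexicon)


@pytest.fixture(scope="session")
def toy_store():
    return generate_embeddings(ToyEmbeddingSpec())


@pytest.fixture(scope="session")
def removals():
    return AmbiguousRemovals.default()
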