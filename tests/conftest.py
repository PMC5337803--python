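import pytest

from aspectsent import GeneratorConfig, fixture_minimal, generate


@pytest.fixture(scope="session")
def minimal():
    """Hand-written 10-tweet fixture with lexicon, gazetteer, abbreviations."""
    return fixture_minimal()


@pytest.fixture(scope="session")
def minimal_lexicon(minimal):
    return minimal.lexicon()

@pytest.fixture(scope="session")
def minimal_gazetteer(minimal):
    return minimal.gazetteer()


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-tweet noiseless synthetic corpus for pipeline-level tests."""
    return generate(GeneratorConfig(n_tweets=60, seed=11))
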