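import pytest

from envminer.geo import default_feature_words, default_gazetteer
from envminer.lexicon import default_dictionary, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def dictionary(lexicon):
    return default_dictionary(lexicon)


@pytest.fixture(scope="session")
def gazetteer():
    return default_gazetteer()


@pytest.fixture(scope="session")
def feature_words():
    return default_feature_words()
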