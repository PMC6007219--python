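import pytest

from orgnorm.fixtures import make_fixture_lexicon
from orgnorm.identify import default_common_terms
from orgnorm.lexicon import build_match_graph


@pytest.fixture(scope="session")
def lexicon():
    return make_fixture_lexicon()


@pytest.fixture(scope="session")
def graph(lexicon):
    return build_match_graph(lexicon)


@pytest.fixture(scope="session")
def common_table():
    return default_common_terms()
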