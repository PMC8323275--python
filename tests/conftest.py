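import pytest

import fangji as fj


@pytest.fixture(scope="session")
def config():
    return fj.GeneratorConfig(seed=42, n_formulas=200)


@pytest.fixture(scope="session")
def corpus_and_truth(config):
    return fj.generate_corpus(config)


@pytest.fixture(scope="session")
def corpus(corpus_and_truth):
    return corpus_and_truth[0]


@pytest.fixture(scope="session")
def dictionary(config):
    return fj.generator_dictionary(config)


@pytest.fixture(scope="session")
def unit_table():
    return fj.default_unit_table()


@pytest.fixture(scope="session")
def index(corpus, dictionary):
    return fj.build_index(corpus, dictionary)


@pytest.fixture(scope="session")
def model():
    return fj.reference_model()
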