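import pytest
from rdkit import RDLogger

from mcsmiles.fixtures import load_curated
from mcsmiles.priors import train_ngrams
from mcsmiles.search_model import build_frequency_matrices

RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def corpus():
    return list(load_curated())


@pytest.fixture(scope="session")
def ngram_model(corpus):
    return train_ngrams(corpus)


@pytest.fixture(scope="session")
def matrices(corpus):
    return build_frequency_matrices(corpus)
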