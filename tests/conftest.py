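import pytest

from neurogloss import annotator, corpus


@pytest.fixture(scope="session")
def kb():
    """The bundled glossary corpus."""
    return corpus.load_bundled_corpus()


@pytest.fixture(scope="session")
def whitelist():
    return corpus.load_whitelist()


@pytest.fixture(scope="session")
def lexicon(kb):
    return annotator.compile_lexicon(kb)
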