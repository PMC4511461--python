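import pytest

from habminer.analysis import LexiconAnalyzer, analyze
from habminer.fixtures import build_fixture_documents, build_fixture_ontology


@pytest.fixture(scope="session")
def ontology():
    return build_fixture_ontology()


@pytest.fixture(scope="session")
def analyzer():
    return LexiconAnalyzer()


@pytest.fixture(scope="session")
def fixture_docs():
    return {doc.doc_id: doc for doc in build_fixture_documents()}


@pytest.fixture(scope="session")
def analyzed(analyzer):
    cache = {}

    def _analyze(text):
        if text not in cache:
            cache[text] = analyze(text, analyzer)
        return cache[text]

    return _analyze
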