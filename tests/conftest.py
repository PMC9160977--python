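import pytest

from mutminer import FixtureSpec, generate_fixtures
from mutminer.corpus_io import Sentence


def make_sentence(text: str, sentence_id: int = 0) -> Sentence:
    return Sentence(sentence_id=sentence_id, start=0, end=len(text), text=text)


@pytest.fixture(scope="session")
def fixture_corpus(tmp_path_factory):
    """The default-condition synthetic corpus: 20 documents, 3 planted
    structured mutations each, decoy rate 0.2, seed 7."""
    root = tmp_path_factory.mktemp("corpus")
    return generate_fixtures(FixtureSpec(), root)


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 3-document corpus with 2 planted mutations each."""
    root = tmp_path_factory.mktemp("small_corpus")
    spec = FixtureSpec(n_documents=3, n_genes=5, mutations_per_document=2,
                       decoy_rate=0.0, random_seed=11)
    return generate_fixtures(spec, root)
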