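import hypothesis
import pytest

from aphasia_surprisal.indices import LexiconTagger
from aphasia_surprisal.synthetic_data import (
    build_default_lexicon,
    default_profiles,
    generate_corpus,
    make_reference_backend,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")

STUDY_SEED = 20240706


@pytest.fixture(scope="session")
def lexicon_and_tags():
    return build_default_lexicon(seed=0)


@pytest.fixture(scope="session")
def lexicon(lexicon_and_tags):
    return lexicon_and_tags[0]


@pytest.fixture(scope="session")
def tagger(lexicon_and_tags):
    _, tag_table = lexicon_and_tags
    return LexiconTagger(
        {r.surface: (r.lemma, r.pos) for r in tag_table.itertuples(index=False)}
    )


@pytest.fixture(scope="session")
def small_corpus(lexicon):
    """10 participants per group: quick module-level checks."""
    return generate_corpus(default_profiles(10), lexicon, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_corpus(lexicon):
    """The packaged study conditions: 50 participants per group."""
    return generate_corpus(default_profiles(50), lexicon, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def reference_backend(lexicon):
    return make_reference_backend(lexicon, n_utterances=2000, seed=STUDY_SEED)
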