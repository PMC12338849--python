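"""Shared fixtures: one trained tokenizer pair and one record batch per run.

Training and generation are the slow parts, so they are session-scoped;
problem sizes (3000 corpus lines, vocabulary 4000, 300 records) are the
package's benchmark defaults at desk scale.
"""

import pytest
from hypothesis import settings

from qrstab import (
    CodecProfile,
    GeneratorProfile,
    ProfileRegistry,
    generate_corpus,
    generate_records,
    load_default_schema,
    train_tokenizer,
)

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

CORPUS_LINES = 3000
VOCAB = 4000
N_RECORDS = 300


@pytest.fixture(scope="session")
def gen_profile():
    return GeneratorProfile(seed=7)


@pytest.fixture(scope="session")
def corpus(gen_profile):
    return generate_corpus(gen_profile, 1, CORPUS_LINES)


@pytest.fixture(scope="session")
def bpe_model(corpus):
    return train_tokenizer(corpus, "bpe", VOCAB, seed=1)


@pytest.fixture(scope="session")
def unigram_model(corpus):
    return train_tokenizer(corpus, "unigram", VOCAB, seed=1)


@pytest.fixture(scope="session")
def schema():
    return load_default_schema()


@pytest.fixture(scope="session")
def codec_profile(bpe_model, schema):
    return CodecProfile(version=1, secret=bytes(range(32)), schema=schema,
                        tokenizer=bpe_model)


@pytest.fixture(scope="session")
def registry(codec_profile):
    return ProfileRegistry().register(codec_profile)


@pytest.fixture(scope="session")
def records(gen_profile):
    return generate_records(gen_profile, N_RECORDS)


@pytest.fixture(scope="session")
def benchmark_result(records, codec_profile):
    from qrstab import run_combos

    return run_combos(records, codec_profile)
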