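"""Toy backends against closed forms and brute-force probability oracles."""

import math
from collections import Counter, defaultdict

import numpy as np
import pytest

from aphasia_surprisal.lm_backend import (
    START,
    UNK,
    NgramBackend,
    SubwordSpan,
    aggregate_span,
    get_backend,
    ngram_backend,
    uniform_backend,
    word_surprisals,
)


class BruteForceNgram:
    """Independent oracle: counts tabulated directly, probabilities by formula."""

    def __init__(self, sentences, order, k):
        self.order, self.k = order, k
        self.vocab = sorted({w for s in sentences for w in s}) + [UNK]
        self.counts = defaultdict(Counter)
        pad = (START,) * (order - 1)
        for s in sentences:
            padded = pad + tuple(s)
            for t in range(len(s)):
                self.counts[padded[t : t + order - 1]][s[t]] += 1

    def prob(self, context, word):
        n_ctx = self.order - 1
        mapped = tuple(
            w if w in self.vocab or w == START else UNK for w in context
        )
        ctx = ((START,) * n_ctx + mapped)[-n_ctx:] if n_ctx else ()
        word = word if word in self.vocab else UNK
        c = self.counts[ctx]
        return (c[word] + self.k) / (sum(c.values()) + self.k * len(self.vocab))

    def sequence_prob(self, words):
        p = 1.0
        for t, w in enumerate(words):
            p *= self.prob(tuple(words[:t]), w)
        return p


def test_uniform_closed_forms():
    assert word_surprisals(uniform_backend(16), ["x"])[0][1] == pytest.approx(4.0)
    assert word_surprisals(uniform_backend(1), ["x"])[0][1] == pytest.approx(0.0)
    nat = uniform_backend(10, log_base=math.e)
    assert word_surprisals(nat, ["x"])[0][1] == pytest.approx(math.log(10))
    surps = [s for _, s in word_surprisals(uniform_backend(8), list("abcde"))]
    assert surps == pytest.approx([3.0] * 5)
    with pytest.raises(ValueError):
        uniform_backend(0)


def test_ngram_smoothing_hand_value():
    # corpus "a b a c", bigrams, k=1, |V|=4 (a,b,c,UNK): P(b|a) = 2/6
    backend = ngram_backend([["a", "b", "a", "c"]], order=2, add_k=1.0)
    surps = word_surprisals(backend, ["a", "b"])
    assert surps[1][1] == pytest.approx(math.log2(3.0))


def test_ngram_deterministic_continuation_limit():
    # corpus "a b a b": as k -> 0+, P(b|a) -> 1, so surprisal of b after a -> 0
    backend = ngram_backend([["a", "b", "a", "b"]], order=2, add_k=1e-12)
    assert word_surprisals(backend, ["a", "b"])[1][1] == pytest.approx(0.0, abs=1e-6)


def test_unknown_word_maps_to_unk():
    corpus = [["the", "girl", "ran", "to", "the", "ball",
               "the", "prince", "saw", "her"]]
    backend = ngram_backend(corpus, order=2, add_k=0.5)
    oracle = BruteForceNgram(corpus, order=2, k=0.5)
    surp = word_surprisals(backend, ["the", "zorp"])[1][1]
    assert surp == pytest.approx(-math.log2(oracle.prob(("the",), UNK)))


def test_chain_rule_against_brute_force():
    rng = np.random.default_rng(42)
    vocab = list("abcdef")
    for _ in range(50):
        n_sent = rng.integers(1, 4)
        sentences = [
            [vocab[i] for i in rng.integers(0, len(vocab), rng.integers(1, 8))]
            for _ in range(n_sent)
        ]
        order = int(rng.integers(1, 4))
        k = float(rng.uniform(0.1, 2.0))
        backend = ngram_backend(sentences, order=order, add_k=k)
        oracle = BruteForceNgram(sentences, order=order, k=k)
        utterance = [vocab[i] for i in rng.integers(0, len(vocab), rng.integers(1, 6))]
        total = sum(s for _, s in word_surprisals(backend, utterance))
        assert total == pytest.approx(
            -math.log2(oracle.sequence_prob(utterance)), abs=1e-9
        )


def test_base_change_identity():
    sentences = [["a", "b", "c", "a", "b"]]
    b2 = ngram_backend(sentences, order=2, add_k=0.5, log_base=2)
    be = ngram_backend(sentences, order=2, add_k=0.5, log_base=math.e)
    s2 = [s for _, s in word_surprisals(b2, ["a", "b", "c"])]
    se = [s for _, s in word_surprisals(be, ["a", "b", "c"])]
    assert se == pytest.approx([math.log(2) * s for s in s2])


def test_count_monotonicity():
    # raising count(a -> b) strictly lowers surprisal of b after a
    low = ngram_backend([["a", "b"], ["a", "c"]], order=2, add_k=1.0)
    high = ngram_backend([["a", "b"], ["a", "b"], ["a", "c"]], order=2, add_k=1.0)
    s_low = word_surprisals(low, ["a", "b"])[1][1]
    s_high = word_surprisals(high, ["a", "b"])[1][1]
    assert s_high < s_low


def test_normalization_audit():
    rng = np.random.default_rng(7)
    sentences = [
        ["w%d" % i for i in rng.integers(0, 10, rng.integers(2, 9))]
        for _ in range(20)
    ]
    backend = ngram_backend(sentences, order=2, add_k=0.3)
    for _ in range(100):
        context = ["w%d" % i for i in rng.integers(0, 12, rng.integers(0, 4))]
        total = sum(backend.conditional_prob(context, w) for w in backend.vocabulary)
        assert total == pytest.approx(1.0, abs=1e-9)


def test_subword_aggregation_modes():
    span = SubwordSpan(0, (2.0, 4.0))
    assert aggregate_span(span, "mean-surprisal") == pytest.approx(3.0)
    assert aggregate_span(span, "sum") == pytest.approx(6.0)
    # mean-prob averages the probabilities, then returns the surprisal
    expected = -math.log2((2**-2.0 + 2**-4.0) / 2)
    assert aggregate_span(span, "mean-prob") == pytest.approx(expected)
    with pytest.raises(ValueError):
        aggregate_span(span, "median")
    with pytest.raises(ValueError):
        SubwordSpan(0, ())


def test_empty_utterance_and_registry():
    backend = uniform_backend(4)
    with pytest.raises(ValueError):
        word_surprisals(backend, [])
    assert get_backend("uniform8").vocab_size == 8
    with pytest.raises(KeyError):
        get_backend("no-such-backend")


def test_cumulative_context_changes_scores():
    sentences = [["a", "b"], ["b", "a"]]
    backend = ngram_backend(sentences, order=2, add_k=0.5)
    isolated = word_surprisals(backend, ["b"])[0][1]
    after_a = word_surprisals(backend, ["b"], preceding=["a"])[0][1]
    assert isolated != after_a
    assert after_a == pytest.approx(
        -math.log2(backend.conditional_prob(["a"], "b"))
    )
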