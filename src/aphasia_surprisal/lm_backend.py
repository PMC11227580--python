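"""Causal language-model backends producing word-level surprisals.

Surprisal of a target word given its left context C under a model M is

    S(w_t | C) = -log_b P_M(w_t | w_1 ... w_{t-1})

with base ``b`` = 2 (bits) by default.  Two self-contained backends (uniform
and add-k smoothed n-gram) make every downstream computation testable against
closed forms; an adapter wraps pre-trained autoregressive transformer models
when the optional ``transformers``/``torch`` stack is installed.

A word split by a model's tokenizer into several subword tokens gets one
surprisal per subtoken; the word-level value is an aggregate over the span
(mean of subtoken surprisals by default; mean of subtoken probabilities and
plain summation are available for sensitivity checks).
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

START = "<s>"
UNK = "<unk>"

SUBWORD_AGGREGATIONS = ("mean-surprisal", "mean-prob", "sum")
CONTEXT_MODES = ("utterance", "cumulative")


@dataclass(frozen=True)
class SubwordSpan:
    """Surprisals of the subword tokens realizing one word."""

    word_index: int
    subtoken_surprisals: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.subtoken_surprisals:
            raise ValueError("a word must map to at least one subtoken")


def aggregate_span(
    span: SubwordSpan, mode: str = "mean-surprisal", log_base: float = 2.0
) -> float:
    """Reduce a subword span to one word surprisal."""
    s = span.subtoken_surprisals
    if mode == "mean-surprisal":
        return sum(s) / len(s)
    if mode == "sum":
        return sum(s)
    if mode == "mean-prob":
        mean_p = sum(log_base**-x for x in s) / len(s)
        return -math.log(mean_p, log_base)
    raise ValueError(f"unknown aggregation {mode!r}; allowed: {SUBWORD_AGGREGATIONS}")


class CausalLMBackend(ABC):
    """Contract: next-token conditional probabilities under left context only."""

    name: str
    log_base: float

    @abstractmethod
    def word_spans(
        self, words: Sequence[str], preceding: Sequence[str] = ()
    ) -> list[SubwordSpan]:
        """Per-word subtoken surprisals for one utterance (teacher forcing).

        ``preceding`` supplies extra left context (earlier utterances) for
        cumulative-context scoring; by default the scoring window resets at
        each utterance.
        """


class ToyBackend(CausalLMBackend):
    """A backend with an explicit finite vocabulary and one subtoken per word.

    Subclasses implement ``conditional_prob``; probabilities over the
    vocabulary must sum to 1 in every context.  The first word of an utterance
    is scored against a start-symbol context so every word has a defined
    surprisal.
    """

    vocabulary: tuple[str, ...]

    @abstractmethod
    def conditional_prob(self, context: Sequence[str], word: str) -> float:
        ...

    def word_spans(
        self, words: Sequence[str], preceding: Sequence[str] = ()
    ) -> list[SubwordSpan]:
        if not words:
            raise ValueError("cannot score an empty utterance")
        left = list(preceding)
        spans = []
        for t, word in enumerate(words):
            p = self.conditional_prob(left + list(words[:t]), word)
            spans.append(
                SubwordSpan(word_index=t, subtoken_surprisals=(-math.log(p, self.log_base),))
            )
        return spans


class UniformBackend(ToyBackend):
    """Every token has probability 1/V in every context (closed-form oracle)."""

    def __init__(self, vocab_size: int, log_base: float = 2.0, name: str | None = None):
        if vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        self.vocab_size = vocab_size
        self.vocabulary = tuple(f"w{i}" for i in range(vocab_size))
        self.log_base = float(log_base)
        self.name = name or f"uniform{vocab_size}"

    def conditional_prob(self, context: Sequence[str], word: str) -> float:
        return 1.0 / self.vocab_size


class NgramBackend(ToyBackend):
    """Add-k smoothed n-gram model:

        P(w | c) = (count(c, w) + k) / (count(c) + k * |V|)

    where the context c is the n-1 most recent words, padded at utterance
    start with a start symbol, and |V| counts the training word types plus an
    unknown-word symbol to which out-of-vocabulary words are mapped.
    """

    def __init__(
        self,
        training_sentences: Iterable[Sequence[str]],
        order: int = 2,
        add_k: float = 1.0,
        log_base: float = 2.0,
        name: str | None = None,
    ):
        if order < 1:
            raise ValueError("order must be >= 1")
        if add_k <= 0:
            raise ValueError("add_k must be > 0")
        sentences = [tuple(s) for s in training_sentences if s]
        if not sentences:
            raise ValueError("training corpus must be non-empty")
        self.order = order
        self.add_k = float(add_k)
        self.log_base = float(log_base)
        self.name = name or f"{order}gram"
        vocab = sorted({w for s in sentences for w in s})
        self.vocabulary = tuple(vocab) + (UNK,)
        self._vocab_set = set(self.vocabulary)
        self._ngram_counts: dict[tuple[str, ...], Counter] = defaultdict(Counter)
        self._context_totals: Counter = Counter()
        pad = (START,) * (order - 1)
        for s in sentences:
            padded = pad + s
            for t in range(len(s)):
                ctx = padded[t : t + order - 1]
                self._ngram_counts[ctx][s[t]] += 1
                self._context_totals[ctx] += 1

    def _map(self, word: str) -> str:
        return word if word in self._vocab_set or word == START else UNK

    def conditional_prob(self, context: Sequence[str], word: str) -> float:
        n_ctx = self.order - 1
        padded = (START,) * n_ctx + tuple(self._map(w) for w in context)
        ctx = padded[len(padded) - n_ctx :] if n_ctx else ()
        w = self._map(word)
        v = len(self.vocabulary)
        num = self._ngram_counts[ctx][w] + self.add_k
        den = self._context_totals[ctx] + self.add_k * v
        return num / den


def uniform_backend(vocab_size: int, log_base: float = 2.0) -> UniformBackend:
    return UniformBackend(vocab_size, log_base=log_base)


def ngram_backend(
    training_sentences: Iterable[Sequence[str]],
    order: int = 2,
    add_k: float = 1.0,
    log_base: float = 2.0,
    name: str | None = None,
) -> NgramBackend:
    return NgramBackend(training_sentences, order=order, add_k=add_k, log_base=log_base, name=name)


class PretrainedBackend(CausalLMBackend):
    """Adapter around a pre-trained autoregressive transformer (GPT-2 family,
    GPT-Neo, Mistral, ...) exposing per-subtoken log probabilities under
    teacher forcing.  Requires the optional ``transformers`` and ``torch``
    dependencies and, on first use of a model id, network access to fetch the
    weights; inference is deterministic for a fixed model revision.
    """

    def __init__(self, model_id: str, log_base: float = 2.0, device: str = "cpu"):
        try:
            import torch  # noqa: F401
            from transformers import AutoModelForCausalLM, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "pretrained backends need the optional 'transformers' and "
                "'torch' dependencies (pip install aphasia-surprisal[pretrained])"
            ) from exc
        self.name = model_id
        self.log_base = float(log_base)
        self._torch = torch
        self._tokenizer = AutoTokenizer.from_pretrained(model_id)
        self._model = AutoModelForCausalLM.from_pretrained(model_id).to(device).eval()
        if self._model.config.is_encoder_decoder or getattr(
            self._model.config, "is_decoder", True
        ) is False:  # pragma: no cover
            raise ValueError(
                f"{model_id} is not a causal (autoregressive) model; masked or "
                "encoder-decoder models do not define left-to-right surprisal"
            )

    def word_spans(
        self, words: Sequence[str], preceding: Sequence[str] = ()
    ) -> list[SubwordSpan]:  # pragma: no cover
        words = tuple(preceding) + tuple(words) if preceding else words
        n_skip = len(preceding)
        if not words:
            raise ValueError("cannot score an empty utterance")
        torch = self._torch
        tok = self._tokenizer
        pieces = [tok.encode(w if i == 0 else " " + w, add_special_tokens=False)
                  for i, w in enumerate(words)]
        bos = tok.bos_token_id
        ids = ([bos] if bos is not None else []) + [i for p in pieces for i in p]
        with torch.no_grad():
            logits = self._model(torch.tensor([ids])).logits[0]
        logprobs = torch.log_softmax(logits, dim=-1)
        offset = 1 if bos is not None else 0
        spans, pos = [], offset
        ln_base = math.log(self.log_base)
        for w_idx, piece in enumerate(pieces):
            surps = []
            for token_id in piece:
                if pos == 0:  # first token with no BOS: undefined context, skip
                    surps.append(0.0)
                else:
                    lp = logprobs[pos - 1, token_id].item()
                    surps.append(-lp / ln_base)
                pos += 1
            if w_idx >= n_skip:
                spans.append(
                    SubwordSpan(word_index=w_idx - n_skip, subtoken_surprisals=tuple(surps))
                )
        return spans


def pretrained_backend(model_id: str, log_base: float = 2.0) -> PretrainedBackend:
    return PretrainedBackend(model_id, log_base=log_base)


def word_surprisals(
    backend: CausalLMBackend,
    words: Sequence[str],
    subword_agg: str = "mean-surprisal",
    preceding: Sequence[str] = (),
) -> list[tuple[str, float]]:
    """One surprisal per word of one utterance, in the backend's log base."""
    if not words:
        raise ValueError("cannot score an empty utterance")
    spans = backend.word_spans(words, preceding=preceding)
    return [
        (words[s.word_index], aggregate_span(s, subword_agg, backend.log_base))
        for s in spans
    ]


# -- registry ---------------------------------------------------------------

_REGISTRY: dict[str, CausalLMBackend] = {}


def register_backend(backend: CausalLMBackend) -> CausalLMBackend:
    _REGISTRY[backend.name] = backend
    return backend


def get_backend(name: str) -> CausalLMBackend:
    if name in _REGISTRY:
        return _REGISTRY[name]
    if name.startswith("uniform"):
        return uniform_backend(int(name.removeprefix("uniform")))
    raise KeyError(
        f"no backend registered under {name!r}; registered: {sorted(_REGISTRY)}"
    )
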