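"""The twelve clinical discourse indices.

Three families of indices computed from POS-tagged, lemmatized utterances:

* productivity/fluency — mean length of utterance (MLU, words per utterance)
  and the number of utterances in the sample;
* lexical diversity — type-token ratio (TTR, unique lemmas over running
  lemmas);
* syntactic complexity — open/closed class ratio, sentence complexity
  (clauses per sentence), nouns over verbs, nouns over prepositions, verb
  ratio V/(V+N), and the noun/verb/adjective/adverb percentages of all words.

Open class = {NOUN, VERB, ADJ, ADV}; everything else, including auxiliaries,
counts as closed class, and auxiliaries are excluded from the verb counts so
"verbs" stay lexical.  Percentages are stored as proportions in [0, 1].
Sentence count equals utterance count under the one-utterance-per-line input
convention.  A zero denominator yields a missing value (NaN), never infinity.

Tagging is pluggable: the deterministic lexicon tagger covers the packaged
synthetic vocabulary; an adapter hook accepts any callable with the same
signature (e.g. wrapping an external statistical tagger).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd

from .transcript_io import Paragraph

logger = logging.getLogger(__name__)

POS_TAGS = (
    "NOUN", "VERB", "ADJ", "ADV", "PRON", "DET", "ADP",
    "CONJ", "AUX", "NUM", "INTJ", "PART", "OTHER",
)
OPEN_CLASS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})

INDEX_NAMES = (
    "mlu", "total_utts", "ttr", "open_close", "sent_complexity",
    "noun_verb", "noun_prep", "verb_ratio",
    "noun_pct", "verb_pct", "adj_pct", "adv_pct",
)


@dataclass(frozen=True)
class TaggedToken:
    surface: str
    lemma: str
    pos: str

    def __post_init__(self) -> None:
        if self.pos not in POS_TAGS:
            raise ValueError(f"unknown POS tag {self.pos!r}")

    @property
    def open_class(self) -> bool:
        return self.pos in OPEN_CLASS


@dataclass(frozen=True)
class IndexVector:
    """The twelve discourse indices for one observation unit."""

    mlu: float
    total_utts: int
    ttr: float
    open_close: float
    sent_complexity: float
    noun_verb: float
    noun_prep: float
    verb_ratio: float
    noun_pct: float
    verb_pct: float
    adj_pct: float
    adv_pct: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


class LexiconTagger:
    """Deterministic tagger backed by a ``surface -> (lemma, pos)`` lexicon.

    Out-of-lexicon words tag as OTHER (closed class) with their surface as
    lemma, logged once per word form.
    """

    def __init__(self, entries: dict[str, tuple[str, str]]):
        self._entries = dict(entries)
        self._warned: set[str] = set()

    @classmethod
    def from_file(cls, path: str | Path) -> "LexiconTagger":
        """Load a delimited ``surface,lemma,pos`` table (header optional)."""
        df = pd.read_csv(path)
        if "surface" not in df.columns:
            df = pd.read_csv(path, header=None, names=["surface", "lemma", "pos"])
        return cls(
            {r.surface: (r.lemma, r.pos) for r in df.itertuples(index=False)}
        )

    def __call__(self, words: Sequence[str]) -> list[TaggedToken]:
        tokens = []
        for w in words:
            if w in self._entries:
                lemma, pos = self._entries[w]
            else:
                if w not in self._warned:
                    logger.warning("word %r not in lexicon; tagged OTHER", w)
                    self._warned.add(w)
                lemma, pos = w, "OTHER"
            tokens.append(TaggedToken(surface=w, lemma=lemma, pos=pos))
        return tokens


Tagger = Callable[[Sequence[str]], list[TaggedToken]]


def tag(utterances: Iterable[Sequence[str]], tagger: Tagger) -> list[list[TaggedToken]]:
    """Tag every (non-empty) utterance of a sample."""
    return [tagger(words) for words in utterances if words]


def fluency_indices(tagged_utterances: Sequence[Sequence[TaggedToken]]) -> tuple[float, int]:
    """(MLU, number of utterances): total words / #utterances, #utterances."""
    if not tagged_utterances:
        raise ValueError("at least one utterance is required")
    n_words = sum(len(u) for u in tagged_utterances)
    return n_words / len(tagged_utterances), len(tagged_utterances)


def lexical_diversity(tagged_utterances: Sequence[Sequence[TaggedToken]]) -> float:
    """Type-token ratio: unique lemmas over running lemmas."""
    lemmas = [t.lemma for u in tagged_utterances for t in u]
    if not lemmas:
        raise ValueError("type-token ratio is undefined on zero tokens")
    return len(set(lemmas)) / len(lemmas)


def count_clauses(tagged_utterance: Sequence[TaggedToken]) -> int:
    """Clause count by the finite-verb heuristic: one clause per lexical VERB.

    Auxiliaries are tagged AUX and do not head clauses; a verb-less fragment
    counts zero clauses.
    """
    return sum(1 for t in tagged_utterance if t.pos == "VERB")


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def syntactic_indices(
    tagged_utterances: Sequence[Sequence[TaggedToken]],
    clause_counts: Sequence[int] | None = None,
) -> dict[str, float]:
    """The nine syntactic-complexity indices, each per its defining formula.

    ``clause_counts`` may supply externally computed per-utterance clause
    counts (e.g. from a dependency parser); by default the finite-verb
    heuristic is used.  Zero-denominator indices come back as NaN.
    """
    tokens = [t for u in tagged_utterances for t in u]
    n_words = len(tokens)
    if n_words == 0:
        raise ValueError("syntactic indices are undefined on zero tokens")
    if clause_counts is None:
        clause_counts = [count_clauses(u) for u in tagged_utterances]
    n = sum(1 for t in tokens if t.pos == "NOUN")
    v = sum(1 for t in tokens if t.pos == "VERB")
    adj = sum(1 for t in tokens if t.pos == "ADJ")
    adv = sum(1 for t in tokens if t.pos == "ADV")
    prep = sum(1 for t in tokens if t.pos == "ADP")
    n_open = sum(1 for t in tokens if t.open_class)
    n_closed = n_words - n_open
    n_sentences = len(tagged_utterances)
    out = {
        "open_close": _ratio(n_open, n_closed),
        "sent_complexity": _ratio(sum(clause_counts), n_sentences),
        "noun_verb": _ratio(n, v),
        "noun_prep": _ratio(n, prep),
        "verb_ratio": _ratio(v, v + n),
        "noun_pct": n / n_words,
        "verb_pct": v / n_words,
        "adj_pct": adj / n_words,
        "adv_pct": adv / n_words,
    }
    for name, value in out.items():
        if isinstance(value, float) and math.isnan(value):
            logger.debug("index %s missing (zero denominator)", name)
    return out


def compute_index_vector(
    tagged_utterances: Sequence[Sequence[TaggedToken]],
    clause_counts: Sequence[int] | None = None,
) -> IndexVector:
    mlu, total_utts = fluency_indices(tagged_utterances)
    ttr = lexical_diversity(tagged_utterances)
    syn = syntactic_indices(tagged_utterances, clause_counts)
    return IndexVector(mlu=mlu, total_utts=total_utts, ttr=ttr, **syn)


def index_table(
    paragraphs: Sequence[Paragraph], tagger: Tagger
) -> pd.DataFrame:
    """Wide per-paragraph table of the twelve indices, aligned with the
    surprisal feature table by participant_id/paragraph_id."""
    rows = []
    for p_idx, paragraph in enumerate(paragraphs):
        tagged = tag(paragraph.words_per_utterance, tagger)
        if not tagged:
            logger.warning(
                "paragraph %s#%d has no taggable utterances; skipped",
                paragraph.participant_id, p_idx,
            )
            continue
        vec = compute_index_vector(tagged)
        rows.append(
            {
                "participant_id": paragraph.participant_id,
                "paragraph_id": f"{paragraph.participant_id}#{p_idx}",
                "group": paragraph.group,
                "subtype": paragraph.subtype,
                **vec.as_dict(),
            }
        )
    return pd.DataFrame(rows)
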