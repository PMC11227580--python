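"""Synthetic discourse corpora with aphasia-like statistical structure.

The generator emulates the shape of story-retell transcripts: per-participant
utterance sequences (aphasia mean ~33 utterances, control ~47), group-
dependent utterance length, omission of function words (agrammatism), a bias
toward nouns over verbs, group-dependent clause-embedding rates, and lexical
substitution (paraphasia-like open-class word swaps).  Utterances are filled
from a template grammar — Det N (Aux) V (Det N) (ADP Det N), with optional
adjectives/adverbs and subordinate-clause embedding — over a deterministic
~500-entry lexicon with Zipf-weighted sampling, so the fixture tagger can
reproduce gold POS tags exactly and gold clause counts are known by
construction.

Every draw derives from one root seed; each participant gets an independent
substream keyed by a stable hash of (seed, participant id), so corpora are
byte-for-byte reproducible and insertion-order independent.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .lm_backend import NgramBackend
from .transcript_io import Transcript, UtteranceRecord

AQ_MAX = 92.8
AQ_MIN = 10.8

_CLOSED_WORDS: dict[str, list[str]] = {
    "DET": ["the", "a", "this", "her", "his", "my", "some"],
    "ADP": ["in", "on", "of", "with", "at", "from", "by", "under"],
    "PRON": ["she", "he", "it", "they", "i", "you", "we"],
    "CONJ": ["and", "but", "because", "when", "that", "so"],
    "AUX": ["is", "was", "are", "were", "has", "had", "will", "can", "did"],
    "NUM": ["one", "two", "three"],
    "INTJ": ["oh", "hey"],
    "PART": ["not"],
}

_ONSETS = ["b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t", "v", "z",
           "br", "dr", "fl", "gr", "kl", "pr", "sl", "tr", "st", "sp"]
_VOWELS = ["a", "e", "i", "o", "u", "ai", "ee", "oa"]
_CODAS = ["", "n", "m", "r", "l", "s", "t", "k", "nd", "rt"]


@dataclass(frozen=True)
class LexiconEntry:
    surface: str
    lemma: str
    pos: str
    open_class: bool
    weight: float


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters for one participant group.

    ``omission_rate`` is the probability a closed-class word is dropped
    (agrammatism), ``noun_bias`` a log-odds boost for a noun intruding into a
    verb slot, ``clause_rate`` the probability of embedding a subordinate
    clause, ``substitution_rate`` the probability an open-class word is
    replaced by a weight-proportional same-POS word.  ``wab_aq_dist`` is
    (mean, sd) truncated to the aphasia severity range; None for controls.
    """

    label: str
    subtype: str
    n_participants: int
    utterances_per_participant: tuple[float, float, int]  # mean, sd, min
    mlu_target: tuple[float, float]  # mean, sd
    omission_rate: float = 0.0
    noun_bias: float = 0.0
    clause_rate: float = 0.0
    substitution_rate: float = 0.0
    wab_aq_dist: tuple[float, float] | None = None
    age_dist: tuple[float, float, float, float] = (50.92, 21.38, 18.0, 89.0)
    sex_p_female: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.omission_rate, self.clause_rate, self.substitution_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.noun_bias < 0:
            raise ValueError("noun_bias must be >= 0")

    @property
    def group(self) -> str:
        return "control" if self.subtype == "none" else "aphasia"


_APHASIA_AGE = (60.17, 10.95, 30.0, 91.0)
_CONTROL_AGE = (50.92, 21.38, 18.0, 89.0)


def default_profiles(n_per_group: int = 50) -> list[GroupProfile]:
    """The packaged study conditions: one control and three aphasia profiles."""
    return [
        GroupProfile(
            label="control", subtype="none", n_participants=n_per_group,
            utterances_per_participant=(47.0, 31.0, 7), mlu_target=(9.0, 3.0),
            omission_rate=0.02, clause_rate=0.30, age_dist=_CONTROL_AGE,
        ),
        GroupProfile(
            label="broca", subtype="Broca", n_participants=n_per_group,
            utterances_per_participant=(33.0, 24.0, 1), mlu_target=(4.5, 2.0),
            omission_rate=0.40, noun_bias=1.0, clause_rate=0.05,
            wab_aq_dist=(55.0, 12.0), age_dist=_APHASIA_AGE,
        ),
        GroupProfile(
            label="wernicke", subtype="Wernicke", n_participants=n_per_group,
            utterances_per_participant=(33.0, 24.0, 1), mlu_target=(8.0, 3.0),
            omission_rate=0.05, substitution_rate=0.30, clause_rate=0.15,
            wab_aq_dist=(65.0, 12.0), age_dist=_APHASIA_AGE,
        ),
        GroupProfile(
            label="anomic", subtype="Anomic", n_participants=n_per_group,
            utterances_per_participant=(33.0, 24.0, 1), mlu_target=(7.0, 3.0),
            omission_rate=0.08, substitution_rate=0.10, clause_rate=0.20,
            wab_aq_dist=(82.0, 8.0), age_dist=_APHASIA_AGE,
        ),
    ]


def _pseudo_words(rng: np.random.Generator, count: int, taken: set[str]) -> list[str]:
    words = []
    while len(words) < count:
        syllables = rng.integers(1, 3 + 1)
        w = "".join(
            _ONSETS[rng.integers(len(_ONSETS))]
            + _VOWELS[rng.integers(len(_VOWELS))]
            + (_CODAS[rng.integers(len(_CODAS))] if s == syllables - 1 else "")
            for s in range(syllables)
        )
        if w not in taken:
            taken.add(w)
            words.append(w)
    return words


def build_default_lexicon(seed: int = 0) -> tuple[list[LexiconEntry], pd.DataFrame]:
    """A deterministic ~500-entry lexicon plus its gold tag table.

    Open-class lemmas are pseudo-words (nouns and verbs carry one inflected
    variant each, sharing the lemma); closed-class words are real English
    function words.  Zipf weights (1/rank) drive sampling.
    """
    rng = np.random.default_rng(seed)
    taken = {w for ws in _CLOSED_WORDS.values() for w in ws}
    entries: list[LexiconEntry] = []

    def add_open(pos: str, n_lemmas: int, inflect: str | None) -> None:
        lemmas = _pseudo_words(rng, n_lemmas, taken)
        for rank, lemma in enumerate(lemmas):
            weight = 1.0 / (rank + 1)
            entries.append(LexiconEntry(lemma, lemma, pos, True, weight))
            if inflect:
                form = lemma + ("d" if lemma.endswith("e") else inflect)
                if form not in taken:
                    taken.add(form)
                    entries.append(LexiconEntry(form, lemma, pos, True, weight / 2))

    add_open("NOUN", 120, "s")
    add_open("VERB", 80, "ed")
    add_open("ADJ", 60, None)
    add_open("ADV", 40, None)
    for pos, words in _CLOSED_WORDS.items():
        for rank, w in enumerate(words):
            entries.append(LexiconEntry(w, w, pos, False, 1.0 / (rank + 1)))
    tag_table = pd.DataFrame(
        [{"surface": e.surface, "lemma": e.lemma, "pos": e.pos} for e in entries]
    )
    return entries, tag_table


class _Sampler:
    """Weight-proportional word sampling, grouped by POS."""

    def __init__(self, lexicon: list[LexiconEntry]):
        self.by_pos: dict[str, list[LexiconEntry]] = {}
        self.probs: dict[str, np.ndarray] = {}
        for e in lexicon:
            self.by_pos.setdefault(e.pos, []).append(e)
        for pos, entries in self.by_pos.items():
            w = np.array([e.weight for e in entries])
            self.probs[pos] = w / w.sum()

    def draw(self, pos: str, rng: np.random.Generator) -> LexiconEntry:
        entries = self.by_pos[pos]
        return entries[rng.choice(len(entries), p=self.probs[pos])]


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


#: baseline probability that a verb slot is intruded by a noun (noun_bias = 0)
_NOUN_INTRUSION_BASE = 0.05


def generate_utterance(
    profile: GroupProfile,
    sampler: _Sampler,
    rng: np.random.Generator,
) -> tuple[list[str], list[tuple[str, str, str]], int]:
    """One utterance: (words, gold (surface, lemma, pos) tags, gold clause count).

    Clauses from the template grammar are appended (coordinated with "and",
    or embedded with "that" at ``clause_rate``) until the length drawn from
    the MLU target is reached, then closed-class omission and open-class
    substitution noise are applied.  The clause count equals the number of
    realized lexical verbs, matching the finite-verb counting heuristic.
    """
    mlu_mean, mlu_sd = profile.mlu_target
    target = max(1, int(round(rng.normal(mlu_mean, mlu_sd))))
    # noun_bias boosts every noun-selection decision: noun fragments intrude
    # into the verb slot, and lexical NPs are preferred over pronoun subjects
    logit0 = math.log(_NOUN_INTRUSION_BASE / (1 - _NOUN_INTRUSION_BASE))
    p_intrude = _sigmoid(logit0 + 2.0 * profile.noun_bias)
    p_pron_scale = math.exp(-2.0 * profile.noun_bias)
    tokens: list[tuple[str, str, str]] = []
    clause_count = 0

    def emit(entry: LexiconEntry) -> None:
        tokens.append((entry.surface, entry.lemma, entry.pos))

    def make_clause(budget: int) -> None:
        nonlocal clause_count
        # subject: pronoun (short) or Det (Adj) N
        if budget <= 3 and rng.random() < 0.5 * p_pron_scale:
            emit(sampler.draw("PRON", rng))
        else:
            emit(sampler.draw("DET", rng))
            if budget >= 6 and rng.random() < 0.4:
                emit(sampler.draw("ADJ", rng))
            emit(sampler.draw("NOUN", rng))
        if budget >= 5 and rng.random() < 0.35:
            emit(sampler.draw("AUX", rng))
        # verb slot, possibly intruded by a noun (agrammatic noun bias)
        if rng.random() < p_intrude:
            emit(sampler.draw("NOUN", rng))
        else:
            if rng.random() < 0.25:
                emit(sampler.draw("ADV", rng))
            emit(sampler.draw("VERB", rng))
            clause_count += 1
        if budget >= 5 and rng.random() < 0.6:  # object NP
            emit(sampler.draw("DET", rng))
            if budget >= 7 and rng.random() < 0.3:
                emit(sampler.draw("ADJ", rng))
            emit(sampler.draw("NOUN", rng))
        if budget >= 8 and rng.random() < 0.4:  # PP adjunct
            emit(sampler.draw("ADP", rng))
            emit(sampler.draw("DET", rng))
            emit(sampler.draw("NOUN", rng))

    make_clause(target)
    while len(tokens) < target:
        if rng.random() < profile.clause_rate:
            emit(LexiconEntry("that", "that", "CONJ", False, 1.0))
        else:
            emit(LexiconEntry("and", "and", "CONJ", False, 1.0))
        make_clause(target - len(tokens))

    noisy: list[tuple[str, str, str]] = []
    for surface, lemma, pos in tokens:
        open_class = pos in ("NOUN", "VERB", "ADJ", "ADV")
        if not open_class and rng.random() < profile.omission_rate:
            continue
        if open_class and rng.random() < profile.substitution_rate:
            sub = sampler.draw(pos, rng)
            noisy.append((sub.surface, sub.lemma, sub.pos))
        else:
            noisy.append((surface, lemma, pos))
    if not noisy:  # every clause carries an open-class word, but guard anyway
        noisy = [tokens[0]]
    words = [surface for surface, _, _ in noisy]
    return words, noisy, clause_count


def _substream(seed: int, participant_id: str) -> np.random.Generator:
    child = zlib.crc32(f"{seed}:{participant_id}".encode()) & 0x7FFFFFFF
    return np.random.default_rng(child)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


@dataclass
class GeneratedCorpus:
    transcripts: list[Transcript]
    manifest: pd.DataFrame
    gold_tags: dict[str, list[list[tuple[str, str, str]]]]
    gold_clauses: dict[str, list[int]] = field(default_factory=dict)


def generate_corpus(
    profiles: list[GroupProfile],
    lexicon: list[LexiconEntry],
    seed: int,
) -> GeneratedCorpus:
    """A full corpus: transcripts, manifest, and gold tags/clause counts."""
    if not profiles:
        raise ValueError("at least one profile is required")
    sampler = _Sampler(lexicon)
    transcripts, rows = [], []
    gold_tags: dict[str, list[list[tuple[str, str, str]]]] = {}
    gold_clauses: dict[str, list[int]] = {}
    for profile in profiles:
        for i in range(profile.n_participants):
            pid = f"{profile.label}{i:03d}"
            rng = _substream(seed, pid)
            u_mean, u_sd, u_min = profile.utterances_per_participant
            n_utts = max(int(u_min), int(round(rng.normal(u_mean, u_sd))))
            records, tags, clauses = [], [], []
            for j in range(n_utts):
                words, gold, n_clauses = generate_utterance(profile, sampler, rng)
                records.append(
                    UtteranceRecord(
                        participant_id=pid, seq_index=j,
                        raw_text=" ".join(words), words=tuple(words),
                        excluded=False,
                    )
                )
                tags.append(gold)
                clauses.append(n_clauses)
            if profile.wab_aq_dist is not None:
                mean_aq, sd_aq = profile.wab_aq_dist
                aq = round(_truncated_normal(rng, mean_aq, sd_aq, AQ_MIN, AQ_MAX), 1)
            else:
                aq = None
            age = round(_truncated_normal(rng, *profile.age_dist), 1)
            sex = "F" if rng.random() < profile.sex_p_female else "M"
            transcripts.append(
                Transcript(
                    participant_id=pid, group=profile.group,
                    subtype=profile.subtype, wab_aq=aq, age=age, sex=sex,
                    utterances=tuple(records),
                )
            )
            rows.append(
                {
                    "participant_id": pid, "group": profile.group,
                    "subtype": profile.subtype, "wab_aq": aq, "age": age,
                    "sex": sex,
                }
            )
            gold_tags[pid] = tags
            gold_clauses[pid] = clauses
    manifest = pd.DataFrame(rows)
    return GeneratedCorpus(
        transcripts=transcripts, manifest=manifest,
        gold_tags=gold_tags, gold_clauses=gold_clauses,
    )


def reference_profile(n_utterances_mean: float = 47.0) -> GroupProfile:
    """A noise-free healthy-language profile for training the reference model."""
    return GroupProfile(
        label="reference", subtype="none", n_participants=1,
        utterances_per_participant=(n_utterances_mean, 0.0, 1),
        mlu_target=(9.0, 3.0), omission_rate=0.0, clause_rate=0.30,
    )


def make_reference_backend(
    lexicon: list[LexiconEntry],
    n_utterances: int = 2000,
    order: int = 2,
    add_k: float = 0.1,
    seed: int = 0,
    log_base: float = 2.0,
) -> NgramBackend:
    """An n-gram backend trained on generated healthy language.

    Stands in for a pre-trained causal language model so that surprisal
    contrasts between healthy-like and aphasia-like text are testable without
    downloads: text with omitted function words or substituted content words
    forms n-grams the healthy training corpus never produced, hence scores
    higher.
    """
    sampler = _Sampler(lexicon)
    profile = reference_profile()
    rng = _substream(seed, "reference-corpus")
    sentences = [
        generate_utterance(profile, sampler, rng)[0] for _ in range(n_utterances)
    ]
    return NgramBackend(
        sentences, order=order, add_k=add_k, log_base=log_base,
        name=f"ref{order}gram",
    )


def corpus_with_omission(
    base: GroupProfile, omission_rate: float, n_per_group: int
) -> GroupProfile:
    """A copy of ``base`` with a different omission rate (for sweeps)."""
    return replace(
        base, label=f"{base.label}_om{int(round(omission_rate * 100)):02d}",
        omission_rate=omission_rate, n_participants=n_per_group,
    )
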