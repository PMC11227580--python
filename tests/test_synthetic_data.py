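"""Generator determinism, designed contrasts, and gold-annotation fidelity."""

import numpy as np
import pytest

from aphasia_surprisal.indices import (
    POS_TAGS,
    count_clauses,
    index_table,
)
from aphasia_surprisal.lm_backend import word_surprisals
from aphasia_surprisal.pipeline import paragraphs_from_transcripts
from aphasia_surprisal.surprisal import utterance_surprisal
from aphasia_surprisal.synthetic_data import (
    GroupProfile,
    _Sampler,
    build_default_lexicon,
    default_profiles,
    generate_corpus,
    generate_utterance,
    make_reference_backend,
)
from aphasia_surprisal.transcript_io import write_corpus

REQUIRED_POS = ("NOUN", "VERB", "ADJ", "ADV", "DET", "ADP", "PRON", "CONJ", "AUX")


def test_lexicon_determinism_and_coverage(tmp_path):
    entries1, table1 = build_default_lexicon(seed=3)
    entries2, table2 = build_default_lexicon(seed=3)
    assert entries1 == entries2
    table1.to_csv(tmp_path / "a.csv", index=False)
    table2.to_csv(tmp_path / "b.csv", index=False)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    by_pos = {pos: [e for e in entries1 if e.pos == pos] for pos in REQUIRED_POS}
    for pos in REQUIRED_POS:
        assert by_pos[pos], f"no lexicon entry for {pos}"
    assert all(e.open_class for e in by_pos["NOUN"])
    assert all(e.weight > 0 for e in entries1)
    assert all(e.pos in POS_TAGS for e in entries1)


def _profile(**kw):
    defaults = dict(
        label="t", subtype="Broca", n_participants=1,
        utterances_per_participant=(5, 0, 1), mlu_target=(8.0, 2.0),
        wab_aq_dist=(60.0, 10.0),
    )
    defaults.update(kw)
    return GroupProfile(**defaults)


def test_utterance_noise_free_limit(lexicon):
    sampler = _Sampler(lexicon)
    rng = np.random.default_rng(0)
    profile = _profile(omission_rate=0.0, substitution_rate=0.0, noun_bias=0.0,
                       clause_rate=0.3)
    for _ in range(50):
        words, tags, clauses = generate_utterance(profile, sampler, rng)
        assert words == [t[0] for t in tags]
        # clause count equals the number of realized lexical verbs
        assert clauses == sum(1 for _, _, pos in tags if pos == "VERB")


def test_omission_boundary(lexicon):
    sampler = _Sampler(lexicon)
    rng = np.random.default_rng(1)
    profile = _profile(omission_rate=1.0)
    open_class = {"NOUN", "VERB", "ADJ", "ADV"}
    for _ in range(25):
        _, tags, _ = generate_utterance(profile, sampler, rng)
        assert all(pos in open_class for _, _, pos in tags)


def test_clause_rate_controls_embedding(lexicon):
    sampler = _Sampler(lexicon)
    rng = np.random.default_rng(2)
    # no embedding: the complementizer "that" never appears, and a single
    # verb-bearing template realizes exactly one clause
    none = _profile(clause_rate=0.0, noun_bias=0.0, mlu_target=(4.0, 0.5))
    for _ in range(50):
        words, _, clauses = generate_utterance(none, sampler, rng)
        assert "that" not in words
        assert clauses >= 1 or all(w not in words for w in ["that"])
    short = _profile(clause_rate=0.0, noun_bias=0.0, mlu_target=(3.0, 0.1))
    singles = [generate_utterance(short, sampler, rng)[2] for _ in range(100)]
    assert max(singles, key=singles.count) == 1
    # heavy embedding at a long target: complementizers do appear
    heavy = _profile(clause_rate=0.9, noun_bias=0.0, mlu_target=(14.0, 1.0))
    seen = [
        "that" in generate_utterance(heavy, sampler, rng)[0] for _ in range(50)
    ]
    assert any(seen)


def test_corpus_reproducibility(tmp_path, lexicon):
    profiles = default_profiles(3)
    c1 = generate_corpus(profiles, lexicon, seed=99)
    c2 = generate_corpus(profiles, lexicon, seed=99)
    assert c1.transcripts == c2.transcripts
    write_corpus(c1.transcripts, tmp_path / "run1")
    write_corpus(c2.transcripts, tmp_path / "run2")
    for f1 in sorted((tmp_path / "run1").iterdir()):
        f2 = tmp_path / "run2" / f1.name
        assert f1.read_bytes() == f2.read_bytes()
    c3 = generate_corpus(profiles, lexicon, seed=100)
    assert c3.transcripts != c1.transcripts


def test_manifest_shape_and_aq_invariant(small_corpus):
    m = small_corpus.manifest
    assert (m.groupby("subtype").size() == 10).all()
    aphasia_aq = m.loc[m["group"] == "aphasia", "wab_aq"]
    assert aphasia_aq.notna().all()
    assert (aphasia_aq <= 92.8).all()
    assert m.loc[m["group"] == "control", "wab_aq"].isna().all()


def test_utterance_count_targets(lexicon):
    corpus = generate_corpus(default_profiles(10), lexicon, seed=5)
    counts = {
        t.participant_id: len(t.utterances) for t in corpus.transcripts
    }
    control = [v for k, v in counts.items() if k.startswith("control")]
    assert abs(np.mean(control) - 47) < 10  # mean target 47 at small n


def test_gold_tags_reproduced_by_fixture_tagger(small_corpus, tagger):
    for t in small_corpus.transcripts[:8]:
        gold = small_corpus.gold_tags[t.participant_id]
        for utt, gold_tags in zip(t.utterances, gold):
            tagged = tagger(list(utt.words))
            assert [(tok.surface, tok.lemma, tok.pos) for tok in tagged] == gold_tags


def test_gold_clauses_match_heuristic(small_corpus, tagger):
    for t in small_corpus.transcripts[:8]:
        gold_counts = small_corpus.gold_clauses[t.participant_id]
        for utt, expected in zip(t.utterances, gold_counts):
            assert count_clauses(tagger(list(utt.words))) == expected


def test_designed_contrasts_recovered(study_corpus, tagger, reference_backend):
    paragraphs = paragraphs_from_transcripts(study_corpus.transcripts, "whole")
    idx = index_table(paragraphs, tagger)
    by = idx.groupby("subtype")[["mlu", "noun_verb", "sent_complexity"]].mean()
    assert by.loc["Broca", "mlu"] < by.loc["none", "mlu"]
    assert by.loc["Broca", "noun_verb"] > by.loc["none", "noun_verb"]
    assert by.loc["Broca", "sent_complexity"] < by.loc["none", "sent_complexity"]

    def mean_surprisal(subtype, n=60):
        paras = [p for p in paragraphs if p.subtype == subtype][:n]
        scores = []
        for p in paras:
            for words in p.words_per_utterance[:5]:
                if words:
                    ws = word_surprisals(reference_backend, list(words))
                    scores.append(utterance_surprisal([s for _, s in ws]))
        return np.mean(scores)

    assert mean_surprisal("Broca") > mean_surprisal("none")


def test_reference_backend_prefers_its_own_language(lexicon, reference_backend):
    rng = np.random.default_rng(17)
    sampler = _Sampler(lexicon)
    healthy = _profile(subtype="none", wab_aq_dist=None, omission_rate=0.0,
                       clause_rate=0.3, mlu_target=(9.0, 3.0))
    utts = [generate_utterance(healthy, sampler, rng)[0] for _ in range(200)]

    def mean_surp(sentences):
        out = []
        for s in sentences:
            ws = word_surprisals(reference_backend, s)
            out.append(utterance_surprisal([x for _, x in ws]))
        return np.mean(out)

    natural = mean_surp(utts)
    for shuffle_seed in range(10):
        r = np.random.default_rng(shuffle_seed)
        shuffled = [list(r.permutation(s)) for s in utts]
        assert natural < mean_surp(shuffled)
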