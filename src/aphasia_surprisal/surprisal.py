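"""Utterance- and paragraph-level surprisal reductions.

An utterance's surprisal is the sum of its word surprisals normalized by the
utterance length (i.e. the mean surprisal per word).  A paragraph's surprisal
is the unweighted mean over its utterances' surprisals — each utterance counts
equally regardless of length.  Empty or excluded utterances are skipped before
reduction because surprisal is undefined on empty input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .lm_backend import CausalLMBackend, word_surprisals
from .transcript_io import Paragraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurprisalProfile:
    """Per-utterance and paragraph-level surprisal under one backend."""

    backend_name: str
    utterance_scores: tuple[float, ...]
    paragraph_score: float


def utterance_surprisal(word_scores: Sequence[float]) -> float:
    """Mean surprisal per word: sum over words divided by utterance length."""
    if len(word_scores) == 0:
        raise ValueError("utterance surprisal is undefined for an empty utterance")
    return float(sum(word_scores)) / len(word_scores)


def paragraph_surprisal(utterance_scores: Sequence[float]) -> float:
    """Unweighted mean of utterance surprisals."""
    if len(utterance_scores) == 0:
        raise ValueError("paragraph surprisal is undefined without utterances")
    return float(sum(utterance_scores)) / len(utterance_scores)


def score_paragraph(
    backend: CausalLMBackend,
    paragraph: Paragraph,
    subword_agg: str = "mean-surprisal",
    context: str = "utterance",
) -> SurprisalProfile:
    """Score every utterance of a paragraph and reduce to the paragraph level.

    ``context="utterance"`` (default) resets the scoring window at every
    utterance; ``"cumulative"`` conditions each utterance on all preceding
    words of the paragraph.
    """
    if context not in ("utterance", "cumulative"):
        raise ValueError("context must be 'utterance' or 'cumulative'")
    scores = []
    preceding: list[str] = []
    for words in paragraph.words_per_utterance:
        if not words:
            continue
        ws = word_surprisals(
            backend,
            words,
            subword_agg=subword_agg,
            preceding=tuple(preceding) if context == "cumulative" else (),
        )
        scores.append(utterance_surprisal([s for _, s in ws]))
        if context == "cumulative":
            preceding.extend(words)
    if not scores:
        raise ValueError("paragraph has no non-empty utterances to score")
    return SurprisalProfile(
        backend_name=backend.name,
        utterance_scores=tuple(scores),
        paragraph_score=paragraph_surprisal(scores),
    )


def surprisal_features(
    paragraph: Paragraph,
    backends: Sequence[CausalLMBackend],
    subword_agg: str = "mean-surprisal",
    context: str = "utterance",
) -> dict[str, float] | None:
    """One paragraph-surprisal value per backend, keyed by backend name.

    Returns ``None`` (and logs) if any backend fails on the paragraph, so the
    caller can drop the observation.
    """
    if not backends:
        raise ValueError("at least one backend is required")
    record: dict[str, float] = {}
    for backend in backends:
        try:
            profile = score_paragraph(
                backend, paragraph, subword_agg=subword_agg, context=context
            )
        except Exception:
            logger.exception(
                "backend %s failed on paragraph %s/%s; observation dropped",
                backend.name,
                paragraph.participant_id,
                paragraph.utterance_indices[:1],
            )
            return None
        record[backend.name] = profile.paragraph_score
    return record


def surprisal_tables(
    paragraphs: Sequence[Paragraph],
    backends: Sequence[CausalLMBackend],
    subword_agg: str = "mean-surprisal",
    context: str = "utterance",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long per-utterance table and wide per-paragraph feature table.

    The long table has columns ``participant_id, paragraph_id, backend,
    utterance_index, utterance_surprisal``; the wide table has one row per
    paragraph with one ``surprisal_<backend>`` column per backend.
    """
    long_rows, wide_rows = [], []
    for p_idx, paragraph in enumerate(paragraphs):
        pid = paragraph.participant_id
        para_id = f"{pid}#{p_idx}"
        wide: dict[str, object] = {
            "participant_id": pid,
            "paragraph_id": para_id,
            "group": paragraph.group,
            "subtype": paragraph.subtype,
        }
        ok = True
        for backend in backends:
            try:
                profile = score_paragraph(
                    backend, paragraph, subword_agg=subword_agg, context=context
                )
            except ValueError:
                logger.warning("dropping unscorable paragraph %s", para_id)
                ok = False
                break
            for u_idx, score in zip(paragraph.utterance_indices, profile.utterance_scores):
                long_rows.append(
                    {
                        "participant_id": pid,
                        "paragraph_id": para_id,
                        "backend": backend.name,
                        "utterance_index": u_idx,
                        "utterance_surprisal": score,
                    }
                )
            wide[f"surprisal_{backend.name}"] = profile.paragraph_score
        if ok:
            wide_rows.append(wide)
    return pd.DataFrame(long_rows), pd.DataFrame(wide_rows)
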