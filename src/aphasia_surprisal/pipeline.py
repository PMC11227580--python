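"""End-to-end glue: transcripts -> paragraphs -> merged feature table.

One row per paragraph carrying the paragraph surprisal under every backend,
the twelve discourse indices, and the participant metadata needed downstream
(group, subtype, WAB-R AQ, age, sex).
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .indices import Tagger, index_table
from .lm_backend import CausalLMBackend
from .surprisal import surprisal_tables
from .transcript_io import Paragraph, Transcript, chunk_paragraphs


def paragraphs_from_transcripts(
    transcripts: Sequence[Transcript], chunk_size: int | str = "whole"
) -> list[Paragraph]:
    out: list[Paragraph] = []
    for t in transcripts:
        out.extend(chunk_paragraphs(t, chunk_size))
    return out


def build_feature_table(
    transcripts: Sequence[Transcript],
    backends: Sequence[CausalLMBackend],
    tagger: Tagger,
    chunk_size: int | str = "whole",
    subword_agg: str = "mean-surprisal",
    context: str = "utterance",
) -> pd.DataFrame:
    """Merged per-paragraph feature table (surprisals + indices + metadata)."""
    paragraphs = paragraphs_from_transcripts(transcripts, chunk_size)
    _, surp_wide = surprisal_tables(
        paragraphs, backends, subword_agg=subword_agg, context=context
    )
    idx_wide = index_table(paragraphs, tagger)
    merged = surp_wide.merge(
        idx_wide.drop(columns=["group", "subtype"]),
        on=["participant_id", "paragraph_id"],
        how="inner",
    )
    meta = pd.DataFrame(
        [
            {
                "participant_id": t.participant_id,
                "wab_aq": t.wab_aq,
                "age": t.age,
                "sex": t.sex,
            }
            for t in transcripts
        ]
    )
    return merged.merge(meta, on="participant_id", how="left")
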