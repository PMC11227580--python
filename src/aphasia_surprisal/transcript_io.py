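"""Reading, cleaning and chunking of discourse transcripts.

Transcripts are UTF-8 plain text, one utterance per line, optionally carrying
a minimal subset of CHAT transcription codes ("CHAT-lite"): ``&=word`` marks a
non-speech verbalization (e.g. laughter) and ``[+ exc]`` marks an extraneous
utterance that must be excluded from analysis.  Any other bracketed span is
deleted without interpretation.  Participant metadata (group, subtype, WAB-R
AQ severity, age, sex) comes from a delimited manifest table.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "aphasia")
SUBTYPES = ("none", "Broca", "Wernicke", "Anomic")

#: WAB-R Aphasia Quotient diagnostic cutoff: AQ <= 92.8 counts as aphasia.
AQ_CUTOFF = 92.8

MANIFEST_COLUMNS = ["participant_id", "group", "subtype", "wab_aq", "age", "sex"]

_EXCLUSION_MARK = re.compile(r"\[\s*\+\s*exc\s*\]")
_NONSPEECH_CODE = re.compile(r"&=\S+")
_BRACKET_SPAN = re.compile(r"\[[^\]]*\]")
_EDGE_PUNCT = re.compile(r"^[^\w]+|[^\w]+$", re.UNICODE)
_HAS_WORD_CHAR = re.compile(r"\w")


@dataclass(frozen=True)
class UtteranceRecord:
    """One utterance after cleaning; ``words`` is empty iff excluded."""

    participant_id: str
    seq_index: int
    raw_text: str
    words: tuple[str, ...]
    excluded: bool


@dataclass(frozen=True)
class Transcript:
    participant_id: str
    group: str
    subtype: str
    wab_aq: float | None
    age: float
    sex: str
    utterances: tuple[UtteranceRecord, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; allowed: {GROUPS}")
        if self.subtype not in SUBTYPES:
            raise ValueError(
                f"unknown subtype {self.subtype!r}; allowed: {SUBTYPES}"
            )
        if self.group == "control" and self.subtype != "none":
            raise ValueError("control participants must have subtype 'none'")

    @property
    def included_utterances(self) -> tuple[UtteranceRecord, ...]:
        return tuple(u for u in self.utterances if not u.excluded)


@dataclass(frozen=True)
class Paragraph:
    """A contiguous run of non-excluded utterances from one transcript."""

    participant_id: str
    utterance_indices: tuple[int, ...]
    words_per_utterance: tuple[tuple[str, ...], ...]
    group: str
    subtype: str

    def __post_init__(self) -> None:
        if not self.utterance_indices:
            raise ValueError("paragraph must contain at least one utterance")
        if list(self.utterance_indices) != sorted(set(self.utterance_indices)):
            raise ValueError("utterance indices must be strictly increasing")


def _clean_word(token: str) -> str:
    """Strip punctuation from word edges, keeping internal apostrophes/hyphens."""
    return _EDGE_PUNCT.sub("", token)


def strip_chat_lite(raw_line: str) -> tuple[list[str], bool]:
    """Clean one raw utterance line.

    Returns ``(words, excluded)``.  ``[+ exc]`` anywhere in the line excludes
    the whole utterance; ``&=...`` codes and other bracketed spans are deleted;
    surviving text is lower-cased and split on whitespace with edge punctuation
    stripped (so "haven't" stays one word).  A line with no word characters
    after cleaning is marked excluded.
    """
    if _EXCLUSION_MARK.search(raw_line):
        return [], True
    text = _NONSPEECH_CODE.sub(" ", raw_line)
    text = _BRACKET_SPAN.sub(" ", text)
    # stray unmatched brackets are unparseable residue, not word material
    text = text.replace("[", " ").replace("]", " ")
    words = []
    for token in text.lower().split():
        word = _clean_word(token)
        if word:
            words.append(word)
        elif _HAS_WORD_CHAR.search(token):
            logger.warning("dropping unparseable residue %r", token)
    if not words:
        return [], True
    return words, False


def parse_transcript_lines(
    participant_id: str, lines: Iterable[str]
) -> tuple[UtteranceRecord, ...]:
    records = []
    for i, line in enumerate(lines):
        words, excluded = strip_chat_lite(line)
        records.append(
            UtteranceRecord(
                participant_id=participant_id,
                seq_index=i,
                raw_text=line.rstrip("\n"),
                words=tuple(words),
                excluded=excluded,
            )
        )
    return tuple(records)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read the participant manifest (CSV or TSV, sniffed from the header)."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    manifest = pd.read_csv(path, sep=sep, dtype={"participant_id": str})
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns {sorted(missing)}")
    if manifest["participant_id"].duplicated().any():
        dupes = manifest.loc[
            manifest["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise ValueError(f"duplicate participant_id in manifest: {dupes}")
    bad_group = ~manifest["group"].isin(GROUPS)
    if bad_group.any():
        raise ValueError(
            f"unknown group labels {sorted(manifest.loc[bad_group, 'group'].unique())}; "
            f"allowed: {list(GROUPS)}"
        )
    bad_sub = ~manifest["subtype"].isin(SUBTYPES)
    if bad_sub.any():
        raise ValueError(
            f"unknown subtype labels {sorted(manifest.loc[bad_sub, 'subtype'].unique())}; "
            f"allowed: {list(SUBTYPES)}"
        )
    return manifest


def load_corpus(
    transcript_paths: Sequence[str | Path], manifest: pd.DataFrame | str | Path
) -> list[Transcript]:
    """Load one :class:`Transcript` per file, joined to its manifest row.

    The participant id is the file stem.  A file without a manifest row, or a
    duplicated participant id, is a hard error.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = load_manifest(manifest)
    rows = manifest.set_index("participant_id")
    transcripts = []
    seen: set[str] = set()
    for p in map(Path, transcript_paths):
        pid = p.stem
        if pid in seen:
            raise ValueError(f"duplicate participant_id {pid!r} ({p})")
        seen.add(pid)
        if pid not in rows.index:
            raise ValueError(f"no manifest row for transcript file {p}")
        row = rows.loc[pid]
        wab_aq = row["wab_aq"]
        transcripts.append(
            Transcript(
                participant_id=pid,
                group=str(row["group"]),
                subtype=str(row["subtype"]),
                wab_aq=None if pd.isna(wab_aq) else float(wab_aq),
                age=float(row["age"]),
                sex=str(row["sex"]),
                utterances=parse_transcript_lines(
                    pid, p.read_text(encoding="utf-8").splitlines()
                ),
            )
        )
    return transcripts


def apply_inclusion(
    transcripts: Iterable[Transcript],
    aq_cutoff: float = AQ_CUTOFF,
    on_missing_aq: str = "error",
) -> list[Transcript]:
    """Keep aphasia-group transcripts with WAB-R AQ <= ``aq_cutoff``.

    Controls pass through untouched.  An aphasia transcript with a missing AQ
    raises by default; with ``on_missing_aq="exclude"`` it is dropped with a
    warning.  The operation is idempotent.
    """
    if on_missing_aq not in ("error", "exclude"):
        raise ValueError("on_missing_aq must be 'error' or 'exclude'")
    kept, removed = [], 0
    for t in transcripts:
        if t.group != "aphasia":
            kept.append(t)
            continue
        if t.wab_aq is None:
            if on_missing_aq == "error":
                raise ValueError(
                    f"aphasia participant {t.participant_id} has no WAB-R AQ"
                )
            logger.warning(
                "excluding %s: missing WAB-R AQ", t.participant_id
            )
            removed += 1
        elif t.wab_aq > aq_cutoff:
            removed += 1
        else:
            kept.append(t)
    if removed:
        logger.info("inclusion rule removed %d transcripts (AQ > %s)", removed, aq_cutoff)
    return kept


def chunk_paragraphs(
    transcript: Transcript, chunk_size: int | str = "whole"
) -> list[Paragraph]:
    """Partition the non-excluded utterances into contiguous paragraphs.

    ``chunk_size="whole"`` yields a single paragraph covering the transcript;
    an integer yields non-overlapping chunks of that many utterances, the last
    possibly shorter.
    """
    included = [u for u in transcript.utterances if not u.excluded]
    if not included:
        raise ValueError(
            f"transcript {transcript.participant_id} has no usable utterances"
        )
    if chunk_size == "whole":
        size = len(included)
    else:
        size = int(chunk_size)
        if size < 1:
            raise ValueError("chunk_size must be >= 1 or 'whole'")
    paragraphs = []
    for start in range(0, len(included), size):
        chunk = included[start : start + size]
        paragraphs.append(
            Paragraph(
                participant_id=transcript.participant_id,
                utterance_indices=tuple(u.seq_index for u in chunk),
                words_per_utterance=tuple(u.words for u in chunk),
                group=transcript.group,
                subtype=transcript.subtype,
            )
        )
    return paragraphs


def write_corpus(
    transcripts: Iterable[Transcript], out_dir: str | Path, cleaned: bool = True
) -> pd.DataFrame:
    """Write one text file per transcript plus ``manifest.csv``; returns the manifest.

    With ``cleaned=True`` each line is the space-joined cleaned words of a
    non-excluded utterance, so re-loading reproduces the words lists exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in transcripts:
        if cleaned:
            lines = [" ".join(u.words) for u in t.utterances if not u.excluded]
        else:
            lines = [u.raw_text for u in t.utterances]
        (out_dir / f"{t.participant_id}.txt").write_text(
            "\n".join(lines) + "\n", encoding="utf-8"
        )
        rows.append(
            {
                "participant_id": t.participant_id,
                "group": t.group,
                "subtype": t.subtype,
                "wab_aq": t.wab_aq,
                "age": t.age,
                "sex": t.sex,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def reindex_cleaned(transcript: Transcript) -> Transcript:
    """Drop excluded utterances and renumber seq_index consecutively from 0."""
    records = tuple(
        replace(u, seq_index=i)
        for i, u in enumerate(transcript.included_utterances)
    )
    return replace(transcript, utterances=records)
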