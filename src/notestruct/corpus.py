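"""Reading, filtering, splitting and segmenting clinical-note text.

The unit of classification is the sentence: nursing narratives are short,
telegraphic texts (mean length around seven tokens) and each sentence is
assumed to fall under exactly one subject heading.  This module provides the
sentence/corpus containers used throughout the package, a rule-table driven
sentence segmenter, a minimum-frequency heading filter and a reproducible
note-level train/dev/test split.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Sentence",
    "LabeledSentence",
    "LabeledCorpus",
    "SegmenterRules",
    "tokenize",
    "segment_sentences",
    "filter_min_frequency",
    "split_corpus",
    "read_corpus_tsv",
    "write_corpus_tsv",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "read_notes_jsonl",
    "write_notes_jsonl",
]

# Tokens: runs of digits possibly holding internal . or , (measurements,
# doses), otherwise runs of word characters. Everything else is dropped.
_TOKEN_RE = re.compile(r"\d+(?:[.,]\d+)*|\w+", re.UNICODE)


def tokenize(text: str) -> list[str]:
    """Lowercase and split ``text`` into word and number tokens.

    Numbers with internal decimal separators (``38.5``) stay single tokens;
    punctuation is discarded.
    """
    return [m.group(0) for m in _TOKEN_RE.finditer(text.lower())]


@dataclass(frozen=True)
class Sentence:
    """One tokenized sentence of a note.

    Attributes
    ----------
    note_id : str
        Identifier of the note the sentence came from.
    index : int
        0-based position of the sentence within its note.
    tokens : tuple of str
        Lowercased word/number tokens.
    raw_text : str
        The original character span.
    """

    note_id: str
    index: int
    tokens: tuple[str, ...]
    raw_text: str

    def __post_init__(self) -> None:
        if self.raw_text.strip() and not self.tokens:
            object.__setattr__(self, "tokens", tuple(tokenize(self.raw_text)))


@dataclass(frozen=True)
class LabeledSentence:
    """A sentence with a gold or predicted subject heading.

    ``confidence`` is the classifier's probability for ``heading`` when the
    label is predicted; ``profile`` optionally carries the full probability
    distribution over the heading inventory (needed by paragraph merging).
    """

    sentence: Sentence
    heading: str
    confidence: float | None = None
    profile: "object | None" = None  # ConfidenceProfile; avoids import cycle

    def __post_init__(self) -> None:
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class LabeledCorpus:
    """A list of labeled sentences plus the heading inventory they draw on."""

    records: list[LabeledSentence]
    heading_inventory: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.heading_inventory:
            self.heading_inventory = {r.heading for r in self.records}
        else:
            missing = {r.heading for r in self.records} - self.heading_inventory
            if missing:
                raise ValueError(f"records use headings outside inventory: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def note_ids(self) -> list[str]:
        """Distinct note ids in first-appearance order."""
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.sentence.note_id, None)
        return list(seen)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_DEFAULT_ABBREVIATIONS = frozenset(
    {
        # common clinical/latin shorthand; lowercased, final period stripped
        "dr", "mr", "mrs", "ms", "prof", "e.g", "i.e", "etc", "vs", "approx",
        "no", "nr", "tel", "klo", "esim", "ym", "mm", "n",
    }
)


@dataclass(frozen=True)
class SegmenterRules:
    """Boundary-rule table for the sentence segmenter.

    A candidate boundary is terminal punctuation (``. ! ?``) followed by
    whitespace or end of text.  A candidate is vetoed when the period sits
    between two digits (decimal numbers) or when the token just before it is
    a known abbreviation.
    """

    abbreviations: frozenset[str] = _DEFAULT_ABBREVIATIONS
    terminals: str = ".!?"


def _is_boundary(text: str, pos: int, rules: SegmenterRules) -> bool:
    """Whether the terminal punctuation ending at index ``pos`` (exclusive)
    closes a sentence."""
    ch = text[pos - 1]
    if ch == ".":
        # decimal number: digit on both sides of the period
        if pos >= 2 and pos < len(text) and text[pos - 2].isdigit() and text[pos].isdigit():
            return False
        # abbreviation: word immediately before the period
        m = re.search(r"[\w.]+$", text[: pos - 1])
        if m and m.group(0).lower().rstrip(".") in rules.abbreviations:
            return False
    return True


def segment_sentences(
    text: str,
    note_id: str = "",
    rules: SegmenterRules | None = None,
) -> list[Sentence]:
    """Split a raw note into :class:`Sentence` objects.

    The concatenation of the returned ``raw_text`` spans reconstructs the
    input modulo whitespace, and indices are consecutive from 0.  Empty or
    whitespace-only input yields an empty list.
    """
    rules = rules or SegmenterRules()
    if not text or not text.strip():
        return []

    boundaries: list[int] = []
    for m in re.finditer(rf"[{re.escape(rules.terminals)}]+(?=\s|$)", text):
        if _is_boundary(text, m.start() + 1, rules):
            boundaries.append(m.end())
    if not boundaries or boundaries[-1] < len(text):
        boundaries.append(len(text))

    sentences: list[Sentence] = []
    start = 0
    carry = ""  # token-less spans (stray punctuation) attach to a neighbour
    for end in boundaries:
        span = text[start:end].strip()
        start = end
        if not span:
            continue
        span = (carry + " " + span).strip() if carry else span
        toks = tuple(tokenize(span))
        if not toks:
            carry = span
            continue
        carry = ""
        sentences.append(Sentence(note_id=note_id, index=len(sentences), tokens=toks, raw_text=span))
    if carry:
        if sentences:
            last = sentences[-1]
            sentences[-1] = Sentence(
                note_id=note_id, index=last.index, tokens=last.tokens,
                raw_text=last.raw_text + " " + carry,
            )
        else:
            sentences.append(Sentence(note_id=note_id, index=0, tokens=(), raw_text=carry))
    return sentences


# ---------------------------------------------------------------------------
# Filtering and splitting
# ---------------------------------------------------------------------------

def filter_min_frequency(corpus: LabeledCorpus, min_count: int) -> LabeledCorpus:
    """Drop every heading used fewer than ``min_count`` times.

    Mirrors the training-data rule of excluding rarely used subject headings;
    records of excluded headings are removed, relative order is preserved.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for r in corpus.records:
        counts[r.heading] = counts.get(r.heading, 0) + 1
    keep = {h for h, c in counts.items() if c >= min_count}
    records = [r for r in corpus.records if r.heading in keep]
    if not records:
        raise ValueError(f"no heading reaches min_count={min_count}; corpus would be empty")
    return LabeledCorpus(records=records, heading_inventory=keep)


def split_corpus(
    corpus: LabeledCorpus,
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[LabeledCorpus, LabeledCorpus, LabeledCorpus]:
    """Partition a corpus into train/dev/test by note id.

    Splitting is note-level so near-duplicate sentences of one note can never
    straddle splits.  Note counts per split follow largest-remainder rounding
    of ``fractions``; the assignment is a pure function of ``seed``.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3:
        raise ValueError("fractions must have exactly three entries")
    if any(f < 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")

    notes = corpus.note_ids()
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(notes) < n_nonzero:
        raise ValueError(f"only {len(notes)} notes for {n_nonzero} non-empty splits")

    rng = np.random.default_rng(seed)
    order = [notes[i] for i in rng.permutation(len(notes))]

    n = len(order)
    raw = [f * n for f in fractions]
    counts = [int(np.floor(x)) for x in raw]
    remainder = n - sum(counts)
    by_frac = sorted(range(3), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in by_frac[:remainder]:
        counts[i] += 1

    assignment: dict[str, int] = {}
    pos = 0
    for split_idx, c in enumerate(counts):
        for nid in order[pos : pos + c]:
            assignment[nid] = split_idx
        pos += c

    buckets: tuple[list[LabeledSentence], ...] = ([], [], [])
    for r in corpus.records:
        buckets[assignment[r.sentence.note_id]].append(r)
    inv = corpus.heading_inventory
    return tuple(  # type: ignore[return-value]
        LabeledCorpus(records=b, heading_inventory=set(inv)) if b else LabeledCorpus(records=[], heading_inventory=set(inv))
        for b in buckets
    )


# ---------------------------------------------------------------------------
# I/O: TSV and JSONL corpora, JSONL notes
# ---------------------------------------------------------------------------

def _record_from_row(note_id: str, text: str, heading: str, index: int) -> LabeledSentence:
    s = Sentence(note_id=str(note_id), index=index, tokens=tuple(tokenize(text)), raw_text=text)
    return LabeledSentence(sentence=s, heading=str(heading))


def read_corpus_tsv(path: str | Path) -> LabeledCorpus:
    """Read a labeled corpus from TSV with columns note_id, sentence_text, heading."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"note_id", "sentence_text", "heading"}
    if not required.issubset(df.columns):
        raise ValueError(f"TSV must have columns {sorted(required)}, got {list(df.columns)}")
    records = []
    idx_within: dict[str, int] = {}
    for row in df.itertuples(index=False):
        i = idx_within.get(row.note_id, 0)
        idx_within[row.note_id] = i + 1
        records.append(_record_from_row(row.note_id, row.sentence_text, row.heading, i))
    return LabeledCorpus(records=records)


def write_corpus_tsv(corpus: LabeledCorpus, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "note_id": [r.sentence.note_id for r in corpus.records],
            "sentence_text": [r.sentence.raw_text for r in corpus.records],
            "heading": [r.heading for r in corpus.records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_corpus_jsonl(path: str | Path) -> LabeledCorpus:
    records = []
    idx_within: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            nid = str(obj["note_id"])
            i = idx_within.get(nid, 0)
            idx_within[nid] = i + 1
            records.append(_record_from_row(nid, obj["sentence_text"], obj["heading"], i))
    return LabeledCorpus(records=records)


def write_corpus_jsonl(corpus: LabeledCorpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in corpus.records:
            fh.write(
                json.dumps(
                    {
                        "note_id": r.sentence.note_id,
                        "sentence_text": r.sentence.raw_text,
                        "heading": r.heading,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_notes_jsonl(path: str | Path) -> list[dict]:
    """Read unstructured notes: one ``{"note_id", "text"}`` object per line."""
    notes = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                notes.append({"note_id": str(obj["note_id"]), "text": str(obj["text"])})
    return notes


def write_notes_jsonl(notes: Iterable[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(json.dumps({"note_id": n["note_id"], "text": n["text"]}, ensure_ascii=False) + "\n")
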