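"""Structuring a free narrative into headed paragraphs.

The pipeline has four steps: (1) segment the note into sentences,
(2) classify each sentence and assign the most confident subject heading,
(3) group same-heading sentences into paragraphs, and (4) optionally merge
paragraphs whose content and headings are close in meaning.  Stopping after
step 3 is the *NoMerging* variant; applying step 4 is *WithMerging*.

Step 4 scores how inclined a source paragraph is towards the heading of a
target paragraph with an asymmetric three-term function

    S(src -> tgt) = mean_{s in src} [ 2 c_s(tgt) - c_s(src) ]
                    - (1 - cos(v_src, v_tgt)) / 2
                    + |tgt| / note_size

where ``c_s(h)`` is the classifier's confidence that sentence ``s`` belongs
under heading ``h`` and ``v_h`` is the heading's learned vector.  The first
term measures how well the source sentences fit under the target heading
(the confidence for the target minus the margin by which the source heading
beats it); the second rewards semantically similar headings; the third
prefers absorbing into larger paragraphs.  With confidences on the
probability simplex the three terms range over [-1, 2], [-1, 0] and (0, 1]
respectively, so S ranges over (-2, 3): supremum 3, infimum -2.

Two paragraphs merge only when *both* directed scores exceed the threshold;
among qualifying pairs the one with the largest mutual similarity
(minimum of the two directions) merges first, the member with the lower
outgoing score keeps its heading, and the matrix is recomputed until no
pair qualifies.  The threshold is calibrated on sample notes so the system
produces approximately the reference number of paragraphs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from notestruct.classifier import (
    ConfidenceProfile,
    HeadingClassifier,
    HeadingVectorSpace,
    heading_vectors,
    predict_confidences,
    top_k,
)
from notestruct.corpus import LabeledSentence, SegmenterRules, segment_sentences

__all__ = [
    "Paragraph",
    "StructuredNote",
    "SimilarityMatrix",
    "MergeConfig",
    "group_into_paragraphs",
    "paragraph_score",
    "similarity_matrix",
    "merge_paragraphs",
    "threshold_response",
    "calibrate_threshold",
    "structure_note",
    "write_structured_jsonl",
    "read_structured_jsonl",
]

SCORE_MIN, SCORE_MAX = -2.0, 3.0


@dataclass(frozen=True)
class Paragraph:
    """An ordered run of sentences sharing one assigned subject heading."""

    heading: str
    sentences: tuple[LabeledSentence, ...]
    note_id: str

    def __post_init__(self) -> None:
        if not self.sentences:
            raise ValueError("paragraph must be non-empty")

    def __len__(self) -> int:
        return len(self.sentences)

    def mean_confidence(self) -> float | None:
        vals = [s.confidence for s in self.sentences if s.confidence is not None]
        return float(np.mean(vals)) if vals else None


@dataclass(frozen=True)
class StructuredNote:
    """Ordered paragraphs with headings; the system's end-to-end output."""

    note_id: str
    paragraphs: tuple[Paragraph, ...]

    def n_sentences(self) -> int:
        return sum(len(p) for p in self.paragraphs)

    def sentence_partition(self) -> list[set[int]]:
        """Sets of sentence indices per paragraph (for partition metrics)."""
        return [{s.sentence.index for s in p.sentences} for p in self.paragraphs]


@dataclass(frozen=True)
class SimilarityMatrix:
    """Directed paragraph-to-paragraph scores; diagonal excluded."""

    n: int
    scores: dict[tuple[int, int], float]

    def __getitem__(self, key: tuple[int, int]) -> float:
        return self.scores[key]


@dataclass(frozen=True)
class MergeConfig:
    """Merging parameters: decision threshold, calibration grid step and an
    iteration guard (None: bounded by the paragraph count)."""

    threshold: float = 0.0
    grid_step: float = 0.05
    max_iterations: int | None = None

    def __post_init__(self) -> None:
        if not (SCORE_MIN <= self.threshold <= SCORE_MAX):
            raise ValueError(f"threshold outside [{SCORE_MIN}, {SCORE_MAX}]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")


# ---------------------------------------------------------------------------
# Step 3: grouping
# ---------------------------------------------------------------------------

def group_into_paragraphs(labeled: Sequence[LabeledSentence]) -> StructuredNote:
    """Group sentences by assigned heading into paragraphs.

    Paragraph order follows the first occurrence of each heading; within a
    paragraph the original note order is kept.
    """
    if not labeled:
        return StructuredNote(note_id="", paragraphs=())
    note_id = labeled[0].sentence.note_id
    groups: dict[str, list[LabeledSentence]] = {}
    for ls in labeled:
        groups.setdefault(ls.heading, []).append(ls)
    paragraphs = tuple(
        Paragraph(heading=h, sentences=tuple(sents), note_id=note_id) for h, sents in groups.items()
    )
    return StructuredNote(note_id=note_id, paragraphs=paragraphs)


# ---------------------------------------------------------------------------
# Step 4: scoring and merging
# ---------------------------------------------------------------------------

def _heading_similarity(vectors: HeadingVectorSpace, a: str, b: str) -> float:
    """Rescaled cosine: -(1 - cos)/2 in [-1, 0]; 0 for identical directions."""
    return -(1.0 - vectors.cosine(a, b)) / 2.0


def paragraph_score(
    src: Paragraph,
    tgt: Paragraph,
    vectors: HeadingVectorSpace,
    note_size: int,
) -> float:
    """Asymmetric similarity of a source paragraph towards a target heading.

    See the module docstring for the three-term definition.  ``note_size``
    is the sentence count of the whole note (the relative-size denominator).
    """
    if src.heading == tgt.heading:
        raise ValueError("source and target paragraphs share a heading")
    if note_size < len(src) + len(tgt):
        raise ValueError("note_size smaller than the two paragraphs")
    terms = []
    for ls in src.sentences:
        prof = ls.profile
        if prof is None:
            raise ValueError(f"sentence {ls.sentence.index} lacks a confidence profile")
        c_tgt = prof.prob_of(tgt.heading)
        c_src = prof.prob_of(src.heading)
        terms.append(2.0 * c_tgt - c_src)
    sentence_term = float(np.mean(terms))
    headsim = _heading_similarity(vectors, src.heading, tgt.heading)
    relsize = len(tgt) / note_size
    return sentence_term + headsim + relsize


def similarity_matrix(note: StructuredNote, vectors: HeadingVectorSpace) -> SimilarityMatrix:
    """Directed score for every ordered paragraph pair of a note."""
    n = len(note.paragraphs)
    if n < 1:
        raise ValueError("note has no paragraphs")
    size = note.n_sentences()
    scores: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(n):
            if i != j:
                scores[(i, j)] = paragraph_score(note.paragraphs[i], note.paragraphs[j], vectors, size)
    return SimilarityMatrix(n=n, scores=scores)


def _merge_pair(note: StructuredNote, i: int, j: int, keep_heading_of: int) -> StructuredNote:
    """Merge paragraphs i and j (i < j); sentences re-sorted to note order;
    the merged paragraph sits at position i."""
    pi, pj = note.paragraphs[i], note.paragraphs[j]
    heading = (pi if keep_heading_of == i else pj).heading
    sentences = tuple(sorted(pi.sentences + pj.sentences, key=lambda ls: ls.sentence.index))
    merged = Paragraph(heading=heading, sentences=sentences, note_id=note.note_id)
    paragraphs = [merged if k == i else p for k, p in enumerate(note.paragraphs) if k != j]
    return StructuredNote(note_id=note.note_id, paragraphs=tuple(paragraphs))


def merge_paragraphs(
    note: StructuredNote,
    vectors: HeadingVectorSpace,
    config: MergeConfig,
) -> StructuredNote:
    """Iteratively merge mutually similar paragraphs (step 4).

    Each round: among pairs whose two directed scores both exceed the
    threshold, merge the pair with the largest mutual similarity
    ``min(S(A->B), S(B->A))`` (ties: lowest index pair); the member with the
    lower outgoing score keeps its heading (it is less inclined to adopt the
    other's, so its own stands; exact ties keep the earlier paragraph's).
    The matrix is recomputed and the process repeats until no pair
    qualifies.
    """
    limit = config.max_iterations if config.max_iterations is not None else max(len(note.paragraphs) - 1, 0)
    iterations = 0
    while len(note.paragraphs) > 1:
        mat = similarity_matrix(note, vectors)
        best: tuple[float, int, int] | None = None
        for i in range(mat.n):
            for j in range(i + 1, mat.n):
                s_ij, s_ji = mat[(i, j)], mat[(j, i)]
                if s_ij > config.threshold and s_ji > config.threshold:
                    mutual = min(s_ij, s_ji)
                    if best is None or mutual > best[0] + 1e-15:
                        best = (mutual, i, j)
        if best is None:
            break
        if iterations >= limit:
            raise RuntimeError("merge did not terminate within max_iterations")
        _, i, j = best
        keep = i if mat[(i, j)] <= mat[(j, i)] else j
        note = _merge_pair(note, i, j, keep_heading_of=keep)
        iterations += 1
    return note


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

def _grid(config: MergeConfig) -> list[float]:
    n = int(round((SCORE_MAX - SCORE_MIN) / config.grid_step))
    return [round(SCORE_MIN + k * config.grid_step, 10) for k in range(n + 1)]


def threshold_response(
    notes_step3: Sequence[StructuredNote],
    vectors: HeadingVectorSpace,
    config: MergeConfig,
) -> list[tuple[float, int]]:
    """Total paragraphs produced at every grid threshold (non-decreasing in
    the threshold: a higher bar forbids more merges)."""
    response = []
    for thr in _grid(config):
        cfg = replace(config, threshold=thr)
        total = sum(len(merge_paragraphs(n, vectors, cfg).paragraphs) for n in notes_step3)
        response.append((thr, total))
    return response


def calibrate_threshold(
    sample: Sequence[tuple[str, int]],
    model: HeadingClassifier,
    vectors: HeadingVectorSpace | None = None,
    config: MergeConfig = MergeConfig(),
    rules: SegmenterRules | None = None,
) -> float:
    """Pick the merge threshold matching reference paragraph counts.

    ``sample`` holds ``(note_text, reference_paragraph_count)`` pairs: notes
    stripped of paragraph information, with the original number of
    paragraphs as the target.  The returned grid threshold minimizes the
    absolute difference between the total number of paragraphs produced and
    the total reference count; ties break towards the larger threshold
    (less merging).
    """
    if not sample:
        raise ValueError("empty calibration sample")
    if any(ref < 1 for _, ref in sample):
        raise ValueError("reference paragraph counts must be >= 1")
    vectors = vectors if vectors is not None else heading_vectors(model)
    notes_step3 = [
        structure_note(text, model, vectors=vectors, rules=rules, note_id=f"cal{i}")
        for i, (text, _) in enumerate(sample)
    ]
    reference = sum(ref for _, ref in sample)
    best_thr, best_err = None, None
    for thr, total in threshold_response(notes_step3, vectors, config):
        err = abs(total - reference)
        # <= so equal error prefers the larger threshold (grid is ascending)
        if best_err is None or err <= best_err:
            best_thr, best_err = thr, err
    return float(best_thr)


# ---------------------------------------------------------------------------
# End-to-end
# ---------------------------------------------------------------------------

def structure_note(
    text: str,
    model: HeadingClassifier,
    vectors: HeadingVectorSpace | None = None,
    threshold: float | None = None,
    rules: SegmenterRules | None = None,
    note_id: str = "",
) -> StructuredNote:
    """Run the pipeline on one raw note.

    Without ``threshold`` the pipeline stops after grouping (NoMerging);
    with it, paragraph merging is applied (WithMerging).  Empty text yields
    an empty note.
    """
    sentences = segment_sentences(text, note_id=note_id, rules=rules)
    if not sentences:
        return StructuredNote(note_id=note_id, paragraphs=())
    labeled = []
    for s in sentences:
        prof = predict_confidences(model, s)
        head, conf = top_k(prof, 1)[0]
        labeled.append(LabeledSentence(sentence=s, heading=head, confidence=conf, profile=prof))
    note = group_into_paragraphs(labeled)
    note = StructuredNote(note_id=note_id, paragraphs=note.paragraphs)
    if threshold is not None:
        vectors = vectors if vectors is not None else heading_vectors(model)
        note = merge_paragraphs(note, vectors, MergeConfig(threshold=threshold))
    return note


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_structured_jsonl(notes: Iterable[StructuredNote], path: str | Path) -> None:
    """Write structured notes as JSONL; each paragraph carries its mean
    classifier confidence so users can judge whether to correct it."""
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            obj = {
                "note_id": note.note_id,
                "paragraphs": [
                    {
                        "heading": p.heading,
                        "sentences": [s.sentence.raw_text for s in p.sentences],
                        "mean_confidence": p.mean_confidence(),
                    }
                    for p in note.paragraphs
                ],
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def read_structured_jsonl(path: str | Path) -> list[dict]:
    with open(path, encoding="utf-8") as fh:
        return [json.loads(line) for line in fh if line.strip()]
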