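"""Automated evaluation metrics and rating-table arithmetic.

Covers top-k heading accuracy on labeled corpora, a pairwise
partition-agreement F1 that serves as the automated proxy for human
judgments of sentence grouping, the paragraph-count reduction achieved by
merging, and percentage summaries of human rating-count tables (heading
ratings 1-4, grouping ratings a-d, and their combinations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from notestruct.classifier import HeadingClassifier, predict_confidences, top_k
from notestruct.corpus import LabeledCorpus
from notestruct.structurer import StructuredNote

__all__ = [
    "RatingTable",
    "top_k_accuracy",
    "pairwise_grouping_f1",
    "paragraph_reduction",
    "paragraphs_per_note",
    "summarize_ratings",
]

HEADING_CLASSES = ("1", "2", "3", "4")
GROUPING_CLASSES = ("a", "b", "c", "d")


def top_k_accuracy(model: HeadingClassifier, test: LabeledCorpus, k: int) -> float:
    """Fraction of sentences whose gold heading is among the model's top-k
    suggestions."""
    if not test.records:
        raise ValueError("empty test corpus")
    n_classes = len(model.classes_)
    if not (1 <= k <= n_classes):
        raise ValueError(f"k={k} out of range [1, {n_classes}]")
    hits = 0
    for r in test.records:
        profile = predict_confidences(model, r.sentence)
        suggested = {h for h, _ in top_k(profile, k)}
        hits += r.heading in suggested
    return hits / len(test.records)


def _same_paragraph_pairs(note: StructuredNote) -> set[tuple[int, int]]:
    pairs: set[tuple[int, int]] = set()
    for block in note.sentence_partition():
        pairs.update(combinations(sorted(block), 2))
    return pairs


def pairwise_grouping_f1(gold: StructuredNote, predicted: StructuredNote) -> tuple[float, float, float]:
    """Precision/recall/F1 over unordered same-paragraph sentence pairs.

    Zero-pair conventions: a side with no same-paragraph pairs contributes
    a perfect score on its own axis (all-singleton vs all-singleton is
    (1, 1, 1)).
    """
    gold_idx = {i for block in gold.sentence_partition() for i in block}
    pred_idx = {i for block in predicted.sentence_partition() for i in block}
    if gold_idx != pred_idx:
        raise ValueError("gold and predicted notes cover different sentence sets")
    G = _same_paragraph_pairs(gold)
    P = _same_paragraph_pairs(predicted)
    tp = len(G & P)
    precision = tp / len(P) if P else 1.0
    recall = tp / len(G) if G else 1.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return precision, recall, f1


def paragraph_reduction(total_before: int, total_after: int) -> float:
    """Percentage drop in paragraph count achieved by merging."""
    if total_before <= 0:
        raise ValueError("total_before must be > 0")
    if not (0 <= total_after <= total_before):
        raise ValueError("total_after must lie in [0, total_before]")
    return 100.0 * (total_before - total_after) / total_before


def paragraphs_per_note(total_paragraphs: int, n_notes: int) -> float:
    """Mean paragraphs per note."""
    if n_notes <= 0:
        raise ValueError("n_notes must be > 0")
    return total_paragraphs / n_notes


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RatingTable:
    """Human rating counts for one system variant.

    ``heading_counts`` holds classes 1 (correct) through 4 (unable to
    assess); ``grouping_counts`` holds classes a (sensible grouping)
    through d.  ``correct_and_sensible`` counts paragraphs rated both 1 and
    a.  All counts refer to ``total_paragraphs`` of the variant.
    """

    variant: str
    total_paragraphs: int
    heading_counts: Mapping[str, int] = field(default_factory=dict)
    grouping_counts: Mapping[str, int] = field(default_factory=dict)
    correct_and_sensible: int | None = None

    def __post_init__(self) -> None:
        if self.total_paragraphs <= 0:
            raise ValueError("total_paragraphs must be > 0")
        for name, counts, classes in (
            ("heading", self.heading_counts, HEADING_CLASSES),
            ("grouping", self.grouping_counts, GROUPING_CLASSES),
        ):
            unknown = set(counts) - set(classes)
            if unknown:
                raise ValueError(f"unknown {name} classes {sorted(unknown)}")
            if counts and sum(counts.values()) != self.total_paragraphs:
                raise ValueError(f"{name} counts do not sum to total_paragraphs")
        if self.correct_and_sensible is not None and not (
            0 <= self.correct_and_sensible <= self.total_paragraphs
        ):
            raise ValueError("correct_and_sensible outside [0, total]")


def summarize_ratings(table: RatingTable) -> dict[str, float]:
    """Per-class percentages (two decimals, round half up) plus the combined
    rows: classes 1+2 (heading at least partly correct) and 1&a (correct
    heading on a sensible grouping)."""
    out: dict[str, float] = {}
    tot = table.total_paragraphs
    for cls, cnt in table.heading_counts.items():
        out[cls] = _round2(100.0 * cnt / tot)
    for cls, cnt in table.grouping_counts.items():
        out[cls] = _round2(100.0 * cnt / tot)
    if {"1", "2"} <= set(table.heading_counts):
        out["1+2"] = _round2(100.0 * (table.heading_counts["1"] + table.heading_counts["2"]) / tot)
    if table.correct_and_sensible is not None:
        out["1&a"] = _round2(100.0 * table.correct_and_sensible / tot)
    return out
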