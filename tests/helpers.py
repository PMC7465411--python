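"""Shared test utilities: mock profiles/paragraphs and independent oracles.

The oracles re-derive the paragraph similarity score and the greedy merge
loop from their definitions with different code (dict-based confidences,
explicit cosine, statistics.fmean) so that agreement with the package is a
genuine cross-check, not a tautology.
"""

from __future__ import annotations

import statistics
from itertools import combinations

import numpy as np

from notestruct.classifier import ConfidenceProfile, HeadingVectorSpace
from notestruct.corpus import LabeledSentence, Sentence
from notestruct.structurer import Paragraph, StructuredNote

_COUNTER = [0]


def make_profile(heads: tuple[str, ...], probs) -> ConfidenceProfile:
    return ConfidenceProfile(heading_ids=tuple(heads), probs=np.asarray(probs, dtype=float))


def make_sentence(index: int, heading: str, profile: ConfidenceProfile | None = None,
                  note_id: str = "n") -> LabeledSentence:
    s = Sentence(note_id=note_id, index=index, tokens=(f"tok{index}",), raw_text=f"tok{index}.")
    return LabeledSentence(sentence=s, heading=heading, profile=profile)


def make_paragraph(heading: str, sentences, note_id: str = "n") -> Paragraph:
    return Paragraph(heading=heading, sentences=tuple(sentences), note_id=note_id)


def vectors_with_cosine(heads: tuple[str, str], cos: float, extra: dict | None = None) -> HeadingVectorSpace:
    """Two 2-d unit vectors with the requested cosine; optional extra rows."""
    a = np.array([1.0, 0.0])
    b = np.array([cos, np.sqrt(max(0.0, 1.0 - cos * cos))])
    rows = {heads[0]: a, heads[1]: b, **(extra or {})}
    ids = tuple(rows)
    return HeadingVectorSpace(heading_ids=ids, vectors=np.array([rows[h] for h in ids]))


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_score(src: Paragraph, tgt: Paragraph, vectors: HeadingVectorSpace, note_size: int) -> float:
    """Paragraph similarity from its verbal definition: per-sentence target
    confidence minus the source-target confidence margin, averaged; plus the
    rescaled heading cosine; plus the target's share of the note."""
    per_sentence = []
    for ls in src.sentences:
        conf = dict(zip(ls.profile.heading_ids, (float(p) for p in ls.profile.probs)))
        per_sentence.append(conf[tgt.heading] - (conf[src.heading] - conf[tgt.heading]))
    va = vectors.vectors[list(vectors.heading_ids).index(src.heading)]
    vb = vectors.vectors[list(vectors.heading_ids).index(tgt.heading)]
    cos = float(np.dot(va, vb) / (np.linalg.norm(va) * np.linalg.norm(vb)))
    head_term = -(1.0 - cos) / 2.0
    return statistics.fmean(per_sentence) + head_term + len(tgt.sentences) / note_size


def oracle_merge(note: StructuredNote, vectors: HeadingVectorSpace, threshold: float) -> StructuredNote:
    """Greedy merge loop re-enumerated from scratch each round."""
    paragraphs = list(note.paragraphs)
    while len(paragraphs) > 1:
        size = sum(len(p.sentences) for p in paragraphs)
        candidates = []
        for i, j in combinations(range(len(paragraphs)), 2):
            s_ij = oracle_score(paragraphs[i], paragraphs[j], vectors, size)
            s_ji = oracle_score(paragraphs[j], paragraphs[i], vectors, size)
            if s_ij > threshold and s_ji > threshold:
                candidates.append((min(s_ij, s_ji), i, j, s_ij, s_ji))
        if not candidates:
            break
        # largest mutual similarity; ties by lowest index pair
        best = max(candidates, key=lambda c: (c[0], (-c[1], -c[2])))
        _, i, j, s_ij, s_ji = best
        keep = paragraphs[i].heading if s_ij <= s_ji else paragraphs[j].heading
        merged = Paragraph(
            heading=keep,
            sentences=tuple(sorted(paragraphs[i].sentences + paragraphs[j].sentences,
                                   key=lambda ls: ls.sentence.index)),
            note_id=note.note_id,
        )
        paragraphs = [merged if k == i else p for k, p in enumerate(paragraphs) if k != j]
    return StructuredNote(note_id=note.note_id, paragraphs=tuple(paragraphs))


def random_mock_note(rng: np.random.Generator, max_paragraphs: int = 4):
    """A random small note with mock profiles and vectors, for oracle
    comparisons of the merge loop."""
    n_par = int(rng.integers(2, max_paragraphs + 1))
    heads = tuple(f"H{k}" for k in range(n_par))
    vecs = HeadingVectorSpace(heading_ids=heads, vectors=rng.normal(size=(n_par, 3)))
    paragraphs = []
    idx = 0
    for h in heads:
        n_sent = int(rng.integers(1, 4))
        sents = []
        for _ in range(n_sent):
            probs = rng.dirichlet(np.ones(n_par))
            sents.append(make_sentence(idx, h, make_profile(heads, probs)))
            idx += 1
        paragraphs.append(make_paragraph(h, sents))
    return StructuredNote(note_id="n", paragraphs=tuple(paragraphs)), vecs


def naive_spearman(r1, r2) -> float:
    """Pearson correlation of the two rank vectors, written out longhand."""
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    a, b = r1 - r1.mean(), r2 - r2.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))
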