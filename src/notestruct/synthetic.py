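"""Synthetic taxonomies and heading-conditioned corpora.

Real nursing-note corpora are not shareable, so every stage of the pipeline
is exercised on generated data with the same statistical shape: a
two-category heading taxonomy (diagnoses and interventions, three levels
under each category, joined by an artificial root), short heading-specific
sentences (token count Poisson with mean 7), paragraphs whose sentence
count is geometric with mean 2.1, and notes drawing a handful of headings
each.

Each leaf heading owns a multinomial topic distribution over an abstract
vocabulary (``w000`` ... tokens; classification behaviour, not linguistics,
is under test), drawn from a symmetric Dirichlet.  A small concentration
parameter makes topics near-disjoint and the corpus separable.
*Conflated pairs* — one diagnosis leaf and one intervention leaf assigned
the *same* topic distribution — plant the real-world phenomenon of
identical content documented under both a diagnosis and an intervention
heading, which the taxonomy-conflict analysis is expected to recover.

Every output is a pure function of the configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from notestruct.corpus import LabeledCorpus, LabeledSentence, Sentence
from notestruct.structurer import Paragraph, StructuredNote
from notestruct.taxonomy import ROOT, HeadingTaxonomy

__all__ = [
    "GeneratorConfig",
    "generate_taxonomy",
    "generate_corpus",
    "generate_unstructured_notes",
]

CATEGORIES = ("diagnosis", "intervention")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.

    Defaults give 10 leaf headings per category (20 total) and roughly 200
    sentences per heading across the corpus: 400 notes x ~5 headings/note
    x ~2.1 sentences/heading / 20 headings.
    """

    n_level1: int = 5
    n_level2: int = 2
    n_level3: int = 1
    vocab_size: int = 500
    topic_concentration: float = 0.05
    mean_sentence_tokens: float = 7.0
    mean_sentences_per_paragraph: float = 2.1
    headings_per_note_min: int = 3
    headings_per_note_max: int = 7
    n_notes: int = 400
    n_conflated_pairs: int = 0
    shuffle_sentences: bool = True
    seed: int = 1

    def __post_init__(self) -> None:
        if min(self.n_level1, self.n_level2, self.n_level3, self.vocab_size, self.n_notes) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.mean_sentence_tokens, self.mean_sentences_per_paragraph, self.topic_concentration) <= 0:
            raise ValueError("means and concentration must be > 0")
        if not (1 <= self.headings_per_note_min <= self.headings_per_note_max):
            raise ValueError("invalid headings-per-note range")


def generate_taxonomy(config: GeneratorConfig) -> HeadingTaxonomy:
    """Two category subtrees of depth 3 under an artificial root.

    Node ids encode their branch (``D2.1.1`` = diagnosis, first-level node
    2, second-level child 1, leaf 1); leaves are the level-3 nodes.  The
    construction is deterministic.
    """
    parent: dict[str, str] = {}
    category: dict[str, str] = {}
    for cat, tag in zip(CATEGORIES, ("D", "I")):
        parent[cat] = ROOT
        category[cat] = cat
        for a in range(1, config.n_level1 + 1):
            l1 = f"{tag}{a}"
            parent[l1] = cat
            category[l1] = cat
            for b in range(1, config.n_level2 + 1):
                l2 = f"{l1}.{b}"
                parent[l2] = l1
                category[l2] = cat
                for c in range(1, config.n_level3 + 1):
                    l3 = f"{l2}.{c}"
                    parent[l3] = l2
                    category[l3] = cat
    return HeadingTaxonomy(parent=parent, category=category, root=ROOT)


# ---------------------------------------------------------------------------
# Topic distributions
# ---------------------------------------------------------------------------

def _category_leaves(tax: HeadingTaxonomy) -> dict[str, list[str]]:
    return {cat: sorted(h for h in tax.leaves() if tax.category.get(h) == cat) for cat in CATEGORIES}


def topic_distributions(tax: HeadingTaxonomy, config: GeneratorConfig) -> dict[str, np.ndarray]:
    """Per-leaf multinomial over the vocabulary; conflated pairs share one.

    The k-th conflated pair is the k-th diagnosis leaf and the k-th
    intervention leaf (sorted order); the intervention leaf inherits the
    diagnosis leaf's distribution, so the pair's content distributions have
    total-variation distance zero.
    """
    by_cat = _category_leaves(tax)
    n_cross = min(len(by_cat["diagnosis"]), len(by_cat["intervention"]))
    if config.n_conflated_pairs > n_cross:
        raise ValueError(
            f"n_conflated_pairs={config.n_conflated_pairs} exceeds available cross-category leaves ({n_cross})"
        )
    rng = np.random.default_rng((config.seed, 0))
    alpha = np.full(config.vocab_size, config.topic_concentration)
    topics: dict[str, np.ndarray] = {}
    for leaf in sorted(tax.leaves()):
        topics[leaf] = rng.dirichlet(alpha)
    for k in range(config.n_conflated_pairs):
        d, i = by_cat["diagnosis"][k], by_cat["intervention"][k]
        topics[i] = topics[d]
    return topics


def conflated_pairs(tax: HeadingTaxonomy, config: GeneratorConfig) -> list[tuple[str, str]]:
    """The planted (diagnosis leaf, intervention leaf) pairs."""
    by_cat = _category_leaves(tax)
    return [
        (by_cat["diagnosis"][k], by_cat["intervention"][k]) for k in range(config.n_conflated_pairs)
    ]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _sample_sentence_tokens(rng: np.random.Generator, topic: np.ndarray, config: GeneratorConfig) -> tuple[str, ...]:
    n = max(1, int(rng.poisson(config.mean_sentence_tokens)))
    idx = rng.choice(config.vocab_size, size=n, p=topic)
    width = max(3, len(str(config.vocab_size - 1)))
    return tuple(f"w{i:0{width}d}" for i in idx)


def _sample_note_paragraphs(
    rng: np.random.Generator,
    leaves: list[str],
    topics: dict[str, np.ndarray],
    config: GeneratorConfig,
) -> list[tuple[str, list[tuple[str, ...]]]]:
    """(heading, sentences-as-token-tuples) blocks for one note."""
    k = int(rng.integers(config.headings_per_note_min, config.headings_per_note_max + 1))
    k = min(k, len(leaves))
    chosen = list(rng.choice(leaves, size=k, replace=False))
    blocks = []
    for heading in chosen:
        n_sent = int(rng.geometric(1.0 / config.mean_sentences_per_paragraph))
        sents = [_sample_sentence_tokens(rng, topics[heading], config) for _ in range(n_sent)]
        blocks.append((heading, sents))
    return blocks


def generate_corpus(tax: HeadingTaxonomy, config: GeneratorConfig) -> LabeledCorpus:
    """A labeled training corpus of heading-conditioned sentences.

    Notes are sequences of heading blocks (paragraphs); only leaf headings
    emit sentences — internal nodes are structural.
    """
    topics = topic_distributions(tax, config)
    leaves = sorted(tax.leaves())
    rng = np.random.default_rng((config.seed, 1))
    records: list[LabeledSentence] = []
    for i in range(config.n_notes):
        note_id = f"note{i:05d}"
        idx = 0
        for heading, sents in _sample_note_paragraphs(rng, leaves, topics, config):
            for toks in sents:
                raw = " ".join(toks) + "."
                s = Sentence(note_id=note_id, index=idx, tokens=toks, raw_text=raw)
                records.append(LabeledSentence(sentence=s, heading=heading))
                idx += 1
    return LabeledCorpus(records=records, heading_inventory=set(leaves))


def generate_unstructured_notes(
    tax: HeadingTaxonomy,
    config: GeneratorConfig,
    n_notes: int | None = None,
) -> list[tuple[str, StructuredNote]]:
    """Free-narrative notes plus their gold paragraph structure.

    Sentences of each note are emitted in shuffled order (narrative style,
    no planned paragraphs); the gold :class:`StructuredNote` keeps the
    heading partition over the emitted sentence positions for scoring.
    With ``shuffle_sentences=False`` the text follows gold paragraph order.
    """
    topics = topic_distributions(tax, config)
    leaves = sorted(tax.leaves())
    rng = np.random.default_rng((config.seed, 2))
    n = n_notes if n_notes is not None else config.n_notes
    out: list[tuple[str, StructuredNote]] = []
    for i in range(n):
        note_id = f"free{i:05d}"
        blocks = _sample_note_paragraphs(rng, leaves, topics, config)
        flat = [(heading, toks) for heading, sents in blocks for toks in sents]
        order = list(rng.permutation(len(flat))) if config.shuffle_sentences else list(range(len(flat)))
        labeled: list[LabeledSentence] = []
        for pos, j in enumerate(order):
            heading, toks = flat[j]
            raw = " ".join(toks) + "."
            s = Sentence(note_id=note_id, index=pos, tokens=toks, raw_text=raw)
            labeled.append(LabeledSentence(sentence=s, heading=heading))
        text = " ".join(ls.sentence.raw_text for ls in labeled)
        groups: dict[str, list[LabeledSentence]] = {}
        for ls in labeled:
            groups.setdefault(ls.heading, []).append(ls)
        gold = StructuredNote(
            note_id=note_id,
            paragraphs=tuple(
                Paragraph(heading=h, sentences=tuple(sents), note_id=note_id)
                for h, sents in groups.items()
            ),
        )
        out.append((text, gold))
    return out
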