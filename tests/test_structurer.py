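"""Paragraph grouping, the asymmetric similarity score, greedy merging and
threshold calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers import (
    make_paragraph,
    make_profile,
    make_sentence,
    oracle_merge,
    oracle_score,
    random_mock_note,
    vectors_with_cosine,
)

from notestruct.classifier import HeadingVectorSpace
from notestruct.structurer import (
    MergeConfig,
    StructuredNote,
    calibrate_threshold,
    group_into_paragraphs,
    merge_paragraphs,
    paragraph_score,
    similarity_matrix,
    structure_note,
    threshold_response,
)

HEADS = ("A", "B", "C")


def _sent(i, heading, probs):
    return make_sentence(i, heading, make_profile(HEADS, probs))


class TestGrouping:
    def test_first_occurrence_order(self):
        labeled = [_sent(0, "A", [1, 0, 0]), _sent(1, "B", [0, 1, 0]), _sent(2, "A", [1, 0, 0])]
        note = group_into_paragraphs(labeled)
        assert [p.heading for p in note.paragraphs] == ["A", "B"]
        assert [s.sentence.index for s in note.paragraphs[0].sentences] == [0, 2]

    def test_all_same_heading_single_paragraph(self):
        labeled = [_sent(i, "C", [0, 0, 1]) for i in range(4)]
        assert len(group_into_paragraphs(labeled).paragraphs) == 1

    def test_all_distinct_note_order(self):
        labeled = [_sent(0, "B", [0, 1, 0]), _sent(1, "C", [0, 0, 1]), _sent(2, "A", [1, 0, 0])]
        assert [p.heading for p in group_into_paragraphs(labeled).paragraphs] == ["B", "C", "A"]

    def test_empty_input(self):
        note = group_into_paragraphs([])
        assert note.paragraphs == ()


class TestParagraphScore:
    def test_worked_example(self):
        # sentence terms 0.0 and 0.3 -> mean 0.15; cosine 0.8 -> -0.1;
        # target 3 of 5 sentences -> 0.6; total 0.65
        src = make_paragraph("A", [_sent(0, "A", [0.6, 0.3, 0.1]), _sent(1, "A", [0.5, 0.4, 0.1])])
        tgt = make_paragraph("B", [_sent(i, "B", [0, 1, 0]) for i in (2, 3, 4)])
        vecs = vectors_with_cosine(("A", "B"), 0.8, extra={"C": np.array([0.0, 1.0])})
        assert paragraph_score(src, tgt, vecs, note_size=5) == pytest.approx(0.65)

    def test_extremes_approach_bounds(self):
        vecs = vectors_with_cosine(("A", "B"), 1.0, extra={"C": np.array([0.0, 1.0])})
        src = make_paragraph("A", [_sent(0, "A", [0.0, 1.0, 0.0])])  # fully confident in B
        tgt = make_paragraph("B", [_sent(i, "B", [0, 1, 0]) for i in range(1, 400)])
        high = paragraph_score(src, tgt, vecs, note_size=400)
        assert 3.0 - 0.01 < high <= 3.0

        anti = vectors_with_cosine(("A", "B"), -1.0, extra={"C": np.array([0.0, 1.0])})
        src2 = make_paragraph("A", [_sent(i, "A", [1.0, 0.0, 0.0]) for i in range(399)])
        tgt2 = make_paragraph("B", [_sent(399, "B", [0, 1, 0])])
        low = paragraph_score(src2, tgt2, anti, note_size=400)
        assert -2.0 <= low < -2.0 + 0.01

    def test_same_heading_rejected(self):
        p = make_paragraph("A", [_sent(0, "A", [1, 0, 0])])
        q = make_paragraph("A", [_sent(1, "A", [1, 0, 0])])
        with pytest.raises(ValueError):
            paragraph_score(p, q, vectors_with_cosine(("A", "B"), 0.5), note_size=2)

    def test_missing_profile_rejected(self):
        src = make_paragraph("A", [make_sentence(0, "A", profile=None)])
        tgt = make_paragraph("B", [_sent(1, "B", [0, 1, 0])])
        with pytest.raises(ValueError):
            paragraph_score(src, tgt, vectors_with_cosine(("A", "B"), 0.5), note_size=2)

    @given(st.data())
    def test_score_within_range_on_random_inputs(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        note, vecs = random_mock_note(rng)
        size = note.n_sentences()
        for i, p in enumerate(note.paragraphs):
            for j, q in enumerate(note.paragraphs):
                if i != j:
                    s = paragraph_score(p, q, vecs, size)
                    assert -2.0 <= s <= 3.0

    def test_matches_verbal_definition_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            note, vecs = random_mock_note(rng)
            size = note.n_sentences()
            for i, p in enumerate(note.paragraphs):
                for j, q in enumerate(note.paragraphs):
                    if i != j:
                        assert paragraph_score(p, q, vecs, size) == pytest.approx(
                            oracle_score(p, q, vecs, size), abs=1e-12
                        )


class TestSimilarityMatrix:
    def test_single_paragraph_empty(self):
        note = StructuredNote("n", (make_paragraph("A", [_sent(0, "A", [1, 0, 0])]),))
        assert similarity_matrix(note, vectors_with_cosine(("A", "B"), 0.5)).scores == {}

    def test_two_paragraphs_two_entries(self):
        note = StructuredNote(
            "n",
            (
                make_paragraph("A", [_sent(0, "A", [0.6, 0.3, 0.1])]),
                make_paragraph("B", [_sent(1, "B", [0.2, 0.7, 0.1])]),
            ),
        )
        mat = similarity_matrix(note, vectors_with_cosine(("A", "B"), 0.5, extra={"C": np.array([0, 1.0])}))
        assert set(mat.scores) == {(0, 1), (1, 0)}

    def test_entries_equal_pairwise_scores(self):
        rng = np.random.default_rng(7)
        note, vecs = random_mock_note(rng)
        mat = similarity_matrix(note, vecs)
        size = note.n_sentences()
        for (i, j), v in mat.scores.items():
            assert v == paragraph_score(note.paragraphs[i], note.paragraphs[j], vecs, size)


class TestMerging:
    def test_threshold_at_supremum_is_identity(self):
        rng = np.random.default_rng(3)
        note, vecs = random_mock_note(rng)
        out = merge_paragraphs(note, vecs, MergeConfig(threshold=3.0))
        assert out == note

    def test_single_paragraph_unchanged(self):
        note = StructuredNote("n", (make_paragraph("A", [_sent(0, "A", [1, 0, 0])]),))
        out = merge_paragraphs(note, vectors_with_cosine(("A", "B"), 0.5), MergeConfig(threshold=-2.0))
        assert out == note

    def test_hand_traced_three_paragraph_merge(self):
        """Paragraphs A and B are mutually above threshold, C is not; A and B
        merge and A keeps the heading (its outgoing score is the lower)."""
        vecs = HeadingVectorSpace(
            heading_ids=HEADS,
            vectors=np.array([[1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]]),  # cos(A,B)=1, cos(*,C)=-1
        )
        pa = make_paragraph("A", [_sent(0, "A", [0.55, 0.40, 0.05])])
        pb = make_paragraph("B", [_sent(1, "B", [0.45, 0.50, 0.05]), _sent(2, "B", [0.40, 0.55, 0.05])])
        pc = make_paragraph("C", [_sent(3, "C", [0.05, 0.05, 0.90])])
        note = StructuredNote("n", (pa, pb, pc))
        # by hand: S(A->B) = (2*.40-.55) + 0 + 2/4 = 0.75
        #          S(B->A) = mean(2*.45-.50, 2*.40-.55) + 0 + 1/4 = 0.575
        #          every score touching C is at most 2*.05-.90 -1 + relsize < 0
        out = merge_paragraphs(note, vecs, MergeConfig(threshold=0.5))
        assert [p.heading for p in out.paragraphs] == ["B", "C"]
        # keep-heading rule: B's outgoing 0.575 < A's outgoing 0.75 -> B keeps
        assert [s.sentence.index for s in out.paragraphs[0].sentences] == [0, 1, 2]

    def test_sentences_conserved_and_coarsened(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            note, vecs = random_mock_note(rng)
            before = sorted(s.sentence.index for p in note.paragraphs for s in p.sentences)
            out = merge_paragraphs(note, vecs, MergeConfig(threshold=0.0))
            after = sorted(s.sentence.index for p in out.paragraphs for s in p.sentences)
            assert before == after
            # every output paragraph is a union of input paragraphs
            in_blocks = [frozenset(s.sentence.index for s in p.sentences) for p in note.paragraphs]
            for p in out.paragraphs:
                members = {s.sentence.index for s in p.sentences}
                union = set()
                for blk in in_blocks:
                    if blk <= members:
                        union |= blk
                assert union == members

    def test_termination_bound(self):
        rng = np.random.default_rng(5)
        note, vecs = random_mock_note(rng, max_paragraphs=4)
        out = merge_paragraphs(note, vecs, MergeConfig(threshold=-2.0))
        # everything mutually above -2 merges down to one paragraph
        assert len(out.paragraphs) == 1

    def test_matches_greedy_oracle_on_small_notes(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            note, vecs = random_mock_note(rng, max_paragraphs=4)
            thr = float(rng.uniform(-1.0, 1.0))
            ours = merge_paragraphs(note, vecs, MergeConfig(threshold=thr))
            ref = oracle_merge(note, vecs, thr)
            assert [p.heading for p in ours.paragraphs] == [p.heading for p in ref.paragraphs]
            assert [tuple(s.sentence.index for s in p.sentences) for p in ours.paragraphs] == [
                tuple(s.sentence.index for s in p.sentences) for p in ref.paragraphs
            ]


class TestCalibration:
    def test_matching_references_return_top_of_grid(self, separable):
        """Distinct-topic notes: step 3 already matches the reference counts,
        so no merging is wanted and the top grid threshold comes back."""
        from notestruct.synthetic import generate_unstructured_notes

        notes = generate_unstructured_notes(separable["taxonomy"], separable["config"], n_notes=8)
        sample = [(text, len(gold.paragraphs)) for text, gold in notes]
        thr = calibrate_threshold(sample, separable["model"], separable["vectors"])
        assert thr == pytest.approx(3.0)

    def test_merging_references_pull_threshold_down(self, separable):
        from notestruct.synthetic import generate_unstructured_notes

        notes = generate_unstructured_notes(separable["taxonomy"], separable["config"], n_notes=20)
        sample = [(text, max(1, len(gold.paragraphs) - 1)) for text, gold in notes]
        thr = calibrate_threshold(sample, separable["model"], separable["vectors"])
        assert thr < 3.0
        produced = sum(
            len(structure_note(text, separable["model"], separable["vectors"], threshold=thr).paragraphs)
            for text, _ in sample
        )
        reference = sum(ref for _, ref in sample)
        assert abs(produced - reference) <= 0.1 * reference

    def test_empty_sample_rejected(self, separable):
        with pytest.raises(ValueError):
            calibrate_threshold([], separable["model"], separable["vectors"])

    def test_zero_reference_rejected(self, separable):
        with pytest.raises(ValueError):
            calibrate_threshold([("some text.", 0)], separable["model"], separable["vectors"])


class TestStructureNote:
    def test_empty_text(self, separable):
        note = structure_note("", separable["model"])
        assert note.paragraphs == ()

    def test_merging_only_coarsens(self, separable, free_notes):
        for text, _ in free_notes[:10]:
            nomerge = structure_note(text, separable["model"], separable["vectors"])
            withmerge = structure_note(text, separable["model"], separable["vectors"], threshold=0.0)
            assert len(withmerge.paragraphs) <= len(nomerge.paragraphs)

    def test_three_planted_topics_recovered_exactly(self, separable):
        """A note assembled from three distinct planted topics structures
        into exactly those three paragraphs."""
        from notestruct.evaluation import pairwise_grouping_f1
        from notestruct.synthetic import GeneratorConfig, generate_unstructured_notes
        import dataclasses

        cfg = dataclasses.replace(
            separable["config"], headings_per_note_min=3, headings_per_note_max=3, shuffle_sentences=True
        )
        notes = generate_unstructured_notes(separable["taxonomy"], cfg, n_notes=5)
        sample = [(text, len(gold.paragraphs)) for text, gold in notes]
        thr = calibrate_threshold(sample, separable["model"], separable["vectors"])
        perfect = 0
        for text, gold in notes:
            pred = structure_note(text, separable["model"], separable["vectors"], threshold=thr)
            _, _, f1 = pairwise_grouping_f1(gold, pred)
            perfect += f1 == pytest.approx(1.0)
        assert perfect >= 4  # near-separable topics; allow one off note

    def test_deterministic(self, separable, free_notes):
        text = free_notes[0][0]
        a = structure_note(text, separable["model"], separable["vectors"], threshold=0.2)
        b = structure_note(text, separable["model"], separable["vectors"], threshold=0.2)
        assert a == b

    def test_output_partitions_segmented_sentences(self, separable, free_notes):
        from notestruct.corpus import segment_sentences

        text = free_notes[1][0]
        note = structure_note(text, separable["model"], separable["vectors"])
        n_seg = len(segment_sentences(text))
        indices = sorted(s.sentence.index for p in note.paragraphs for s in p.sentences)
        assert indices == list(range(n_seg))


def test_threshold_response_is_monotone_small(separable):
    from notestruct.synthetic import generate_unstructured_notes

    notes = generate_unstructured_notes(separable["taxonomy"], separable["config"], n_notes=6)
    step3 = [structure_note(t, separable["model"], separable["vectors"]) for t, _ in notes]
    resp = threshold_response(step3, separable["vectors"], MergeConfig(grid_step=0.25))
    totals = [c for _, c in resp]
    assert totals == sorted(totals)
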