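# notestruct

Automatic structuring of free-text nursing narratives under subject
headings.

Nurses in many care systems must document under a standardized heading
taxonomy (hundreds of subject headings covering nursing *diagnoses* and
*interventions*), which makes narrative documentation slow and error-prone.
`notestruct` implements a system that lets a nurse write (or dictate) a
note as free narrative and then structures it automatically, in four
steps:

1. **segment** the note into sentences (rule-table segmenter aware of
   decimal numbers and clinical abbreviations);
2. **classify** every sentence into a subject heading with a multiclass
   sentence classifier, keeping the full confidence profile
   `c_s(·)` over the heading inventory;
3. **group** same-heading sentences into paragraphs (the *NoMerging*
   variant stops here);
4. **merge** paragraphs that carry near-synonymous headings
   (*WithMerging*), using an asymmetric paragraph-to-paragraph score

   ```
   S(src → tgt) = mean_{s ∈ src} [ 2·c_s(tgt) − c_s(src) ]
                  − (1 − cos(v_src, v_tgt)) / 2
                  + |tgt| / |note|
   ```

   where `v_h` is the learned heading vector (the heading's row of the
   classifier's output layer).  `S` ranges over (−2, 3].  Two paragraphs
   merge when both directed scores exceed a threshold; the threshold is
   calibrated so the system produces approximately as many paragraphs as
   reference notes contain.

The package also ships the **taxonomy-conflict analysis**: all heading
pairs are ranked once by cosine distance between learned heading vectors
(how headings are *used*) and once by shortest-path distance in the heading
taxonomy (how they are *intended* to be used); the pairs furthest apart in
the two rankings expose documentation-practice conflicts, typically a
diagnosis heading and an intervention heading documenting identical content
("Swelling" vs "Monitoring Swelling").

Clinical corpora of this kind cannot be shared, so a first-class synthetic
generator (`notestruct.synthetic`) reproduces the statistical shape of the
data — two-category depth-3 taxonomy, ~7-token sentences, ~2.1 sentences
per paragraph, Dirichlet topic distributions per heading, and plantable
cross-category *conflated pairs* with identical content distributions —
making every stage testable end to end.

## Worked example

```python
import numpy as np
from notestruct import (
    ClassifierConfig, GeneratorConfig, generate_taxonomy, generate_corpus,
    generate_unstructured_notes, split_corpus, train_classifier,
    heading_vectors, calibrate_threshold, structure_note,
)
from notestruct.evaluation import pairwise_grouping_f1, top_k_accuracy

cfg = GeneratorConfig(seed=1)                       # 20 leaf headings
tax = generate_taxonomy(cfg)
corpus = generate_corpus(tax, cfg)                  # ~4200 labeled sentences
train, dev, test = split_corpus(corpus, (0.6, 0.2, 0.2), seed=1)
model = train_classifier(
    train, dev, ClassifierConfig(backend="bow_softmax", max_epochs=100, patience=10, seed=1)
)
print(f"held-out top-1 accuracy: {top_k_accuracy(model, test, 1):.3f}")

vectors = heading_vectors(model)
notes = generate_unstructured_notes(tax, cfg, n_notes=40)
sample = [(text, len(gold.paragraphs)) for text, gold in notes[:20]]
threshold = calibrate_threshold(sample, model, vectors)
print(f"calibrated merge threshold: {threshold:.2f}")

f1s = [
    pairwise_grouping_f1(gold, structure_note(text, model, vectors, threshold=threshold))[2]
    for text, gold in notes
]
print(f"mean pairwise grouping F1 over 40 notes: {np.mean(f1s):.3f}")
```

prints

```
held-out top-1 accuracy: 0.988
calibrated merge threshold: 3.00
mean pairwise grouping F1 over 40 notes: 0.983
```

The classifier recovers the planted topics almost perfectly (98.8% of
held-out sentences get their true heading), and the structured notes agree
with the planted paragraph partition at F1 0.983.  The calibration returns
the top of the threshold grid here because the step-3 output already
matches the reference paragraph counts — with distinct topics no merging is
wanted.  When reference notes contain fewer paragraphs than step 3
produces (headings used interchangeably), calibration settles below the
top of the grid and the merge step contracts the structure accordingly.

Each output paragraph carries its mean classifier confidence, so
downstream users can see which paragraphs may need manual correction.

A command-line interface covers the same workflow on files:

```bash
notestruct generate --out-dir data/ --seed 1
notestruct train --corpus data/corpus.tsv --model model/ --backend bow_softmax
notestruct calibrate --model model/ --sample data/gold.jsonl --out thr.json
notestruct structure --model model/ --notes data/notes.jsonl --mode merge \
    --threshold 3.0 --out structured.jsonl
notestruct evaluate --gold data/gold.jsonl --pred structured.jsonl --report report.json
```

## Classifier backends

* `bow_softmax` — multinomial logistic regression on bag-of-words counts;
  fast, deterministic, used throughout the test suite.  Heading vectors
  have vocabulary width.
* `recurrent` — bidirectional recurrent network over pretrained (PPMI +
  SVD) word embeddings; per-direction hidden width `h`, heading vectors of
  width `2h` (1200 at the production setting of 600 per direction).

Both backends expose the same estimator interface (scikit-learn style
`fit` / `predict` / `predict_proba`) and the whole downstream pipeline is
backend-agnostic.

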