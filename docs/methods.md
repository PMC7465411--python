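# Methods

This note records the models and procedures implemented in `notestruct`,
the parameters that matter, the design choices that were genuinely open,
and what the synthetic test conditions do and do not establish.

## Task and units

The system turns a free nursing narrative into an ordered list of
paragraphs, each labelled with one subject heading from a care
classification inventory.  The unit of classification is the sentence;
every sentence is assumed to belong under exactly one heading.  Clinical
sentences of this genre are short and telegraphic (the generator targets a
mean of 7 tokens), so sentence-level classification with a bag-of-words or
a small recurrent encoder is a reasonable operating point.

## Sentence segmentation

A candidate boundary is terminal punctuation (`. ! ?`) followed by
whitespace or end of text.  Two veto rules ship in the default rule table:
a period flanked by digits (decimal measurements such as `38.5`) and a
period following a known abbreviation (configurable list; clinical and
Latin shorthand).  Token-less spans (stray punctuation) attach to a
neighbouring sentence so that the concatenation of spans reconstructs the
input modulo whitespace.  The rule table is deliberately small and
config-driven: boundary conventions differ across hospitals and languages,
and the table is the extension point.  Tokenization lowercases, splits on
whitespace and punctuation, and keeps numbers (including decimal forms) as
single tokens.

## Classifier

Two backends behind one estimator:

* **bow_softmax** — multinomial logistic regression over bag-of-words
  counts, trained full-batch with Adam (learning rate 0.01, L2 1e-4 on the
  output weights), zero-initialized.  Zero initialization matters for the
  conflict analysis: classes with identical input distributions receive
  near-identical weight rows by symmetry rather than by accident of
  initialization.
* **recurrent** — an embedding layer initialized from pretrained vectors,
  a bidirectional Elman recurrent layer (tanh, hidden width `h` per
  direction, final states of the two directions concatenated), and a
  softmax output layer; trained by backpropagation through time with Adam
  on minibatches of 32.  Defaults mirror the production-scale setting
  (300-d embeddings, 600 per direction); tests run it at desk scale
  (8–16-d, a few epochs), where it reaches the same near-perfect accuracy
  on the separable synthetic task.

Early stopping for both backends monitors development-set top-1 accuracy
with a patience counted in epochs, and restores the best-epoch parameters.
Training is single-threaded numpy and exactly reproducible at a fixed
seed.

Word embeddings are pretrained from corpus co-occurrence statistics:
a symmetric 5-token window count matrix, positive pointwise mutual
information, truncated SVD, rows scaled by the square root of the singular
values, with a deterministic sign convention.  This count-based
factorization gives the property the pipeline actually relies on — tokens
used in identical contexts get identical vectors — and is exactly
reproducible.  Whether embeddings stay trainable during classifier
training is a config flag (`freeze_embeddings`, default trainable).

Empty sentences receive the uniform confidence profile (with a warning)
rather than an error, since narratives contain such lines; fully
out-of-vocabulary sentences are canonicalized to a single unknown token so
that any two of them share one profile.

**Heading vectors.**  The rows of the output layer are used as semantic
representations of the headings: two headings with similar rows get
similar probabilities for any input, so headings used for similar
sentences end up close.  The output bias is excluded — it encodes class
priors, not usage.  Width is `2h` for the recurrent backend and the
vocabulary size for bow_softmax.

## Paragraph scoring and merging

The directed score of a source paragraph towards a target heading is

    S(src → tgt) = mean_{s∈src} [2·c_s(tgt) − c_s(src)]
                   − (1 − cos(v_src, v_tgt))/2
                   + |tgt| / note_size

Term by term: the confidence a sentence assigns the target heading, minus
the margin by which its own heading beats the target, averaged over the
source paragraph (range [−1, 2] for profiles on the simplex); a rescaled
cosine between the heading vectors (range [−1, 0], 0 for identical
directions); and the target paragraph's share of the note (range (0, 1]).
The total therefore spans (−2, 3), with supremum 3 and infimum −2
approached by extremal constructions.  The sign and scale of the heading
term is a design choice: the verbal description "summed with the cosine
distance" conflicts with the requirement that more similar headings be
more likely to merge, and `−(1−cos)/2` is the unique natural variant under
which similarity helps *and* the total score spans exactly [−2, 3].

Merging is greedy: among pairs whose two directed scores both exceed the
threshold (strictly), the pair with the largest mutual similarity
`min(S(A→B), S(B→A))` merges first; ties break to the lowest index pair.
The merged paragraph keeps the heading of the member with the **lower
outgoing** score — that member is less inclined to adopt the other's
heading, so its own stands; exact ties keep the earlier paragraph's
heading.  Sentences are re-sorted to note order, the matrix is recomputed,
and the loop repeats until no pair qualifies (at most `n−1` merges).
Merged sentences keep their original confidence profiles; nothing is
re-classified after a merge.

**Calibration.**  The threshold is chosen on a grid over [−2, 3] (default
step 0.05) to minimize the absolute difference between the *total* number
of paragraphs produced on a calibration sample and the total in the
reference versions, with ties resolved towards the larger threshold (less
merging).  Totals rather than per-note means are matched; with the
absolute-difference objective the two disagree only in corner cases.  The
produced total is a non-decreasing step function of the threshold, which
the suite exercises across the grid.

## Taxonomy analysis

The heading taxonomy is a rooted tree: an artificial root joins the
diagnosis and intervention category nodes, each carrying a three-level
hierarchy (maximum node depth 4).  Heading-to-heading distance is the
edge count of the unique connecting path (computed via root paths and the
lowest common ancestor; cross-checked against breadth-first search in the
suite).

For the conflict analysis, all unordered heading pairs are ranked twice:
by cosine distance between heading vectors and by tree distance.  Tree
distances are small integers, so ties are pervasive; fractional (average)
ranks keep the rankings comparable, and the rank correlation is the
tie-corrected Spearman rho.  Conflicts in the `model_close_tree_far`
direction are pairs maximizing `rank_tree − rank_model`; the opposite
direction is exposed symmetrically, since either sign of the discrepancy
is informative.  Headings are mapped into the taxonomy by exact string
match on identifiers; unmapped headings are dropped from the analysis set.
Hierarchical clustering of the heading vectors (cosine distance, average
linkage by default; the linkage is a free choice) is exported as Newick
with merge heights as branch lengths for dendrogram inspection.

## Synthetic data

The generator emulates the statistical shape of heading-structured nursing
corpora rather than their language: abstract tokens (`w017`), one
multinomial topic distribution per leaf heading drawn from a symmetric
Dirichlet over a 500-token vocabulary.  Defaults, chosen once as the
study conditions:

| parameter | default | meaning |
|---|---|---|
| branching per category | 5 × 2 × 1 | 10 leaf headings per category, 20 total |
| topic_concentration | 0.05 | near-disjoint topics (separable regime) |
| mean_sentence_tokens | 7 | Poisson sentence length (min 1) |
| mean_sentences_per_paragraph | 2.1 | geometric, support ≥ 1 |
| headings per note | Uniform{3..7} | sampled without replacement, leaves only |
| n_notes | 400 | ≈ 210 sentences per heading |

Only leaf headings emit sentences; internal nodes are structural.
*Conflated pairs* plant the documented real-world failure mode: the k-th
diagnosis leaf and k-th intervention leaf share one topic distribution
(total-variation distance zero), so no classifier can separate them and
their learned heading vectors should coincide — the conflict analysis is
expected to surface exactly these pairs.  Free-narrative notes emit their
sentences in shuffled order (toggleable) and keep the gold heading
partition for scoring.

What the synthetic conditions do **not** show: robustness to real clinical
language (morphology, misspellings, multi-topic sentences), to
heading-inventory drift between standards, or to the much weaker class
separability of real data, where sentence-level accuracy is far below the
desk-scale 0.99.  Passing the recovery suite establishes that the
machinery is correct, not that real-data performance transfers.

## Evaluation

`pairwise_grouping_f1` scores a predicted partition against gold over
unordered same-paragraph sentence pairs (precision/recall/F1; a side with
no pairs scores 1.0 on its own axis, so all-singletons vs all-singletons
is (1,1,1)).  It is the automated stand-in for human assessments of
grouping quality, which required domain experts in the original setting.
`top_k_accuracy` measures whether the gold heading is among the k most
confident suggestions.  Rating tables (heading classes 1–4, grouping
classes a–d, and the combined 1+2 and 1∧a rows) are summarized as
percentages with two-decimal round-half-up, matching the presentation
convention of such evaluations; the package performs only the counting
arithmetic, not any modelling of rater judgment.

## Numerical choices and degenerate inputs

- Probabilities validated to sum to 1 within 1e-6; profile/heading
  mismatches raise.
- Zero heading vectors raise (cosine undefined), naming the heading.
- `top_k` and conflict orderings break ties deterministically by
  identifier.
- The merge loop carries an iteration guard even though each merge
  strictly reduces the paragraph count.
- `split_corpus` splits at note level (sentences of one note never
  straddle splits, preventing near-duplicate leakage) and allocates note
  counts by largest-remainder rounding, so equal-sized fractions give
  exact splits.
- Heading-frequency filtering is strict (`< min_count` excluded) and
  idempotent.

## Problem sizes

The suite and the acceptance script run the full pipeline at the default
synthetic conditions (20 headings, ~4200 sentences, 40–50 evaluation
notes) with the bow_softmax backend; the recurrent backend is exercised at
reduced width.  These sizes were chosen as the smallest at which the
separable-recovery claims are statistically stable across seeds.
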