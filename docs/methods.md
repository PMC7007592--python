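# Methods

## Problem and pipeline

The package classifies patients from free-text clinical notes using
expert-authored regular-expression features. The pipeline is fixed:

1. **Segmentation.** Each note is split into sentences (rules below).
2. **Per-sentence counting.** For each sentence, the number of
   non-overlapping matches of each feature is counted; one coordinate per
   feature.
3. **Per-note summation.** Sentence count vectors are summed over the
   note.
4. **Per-patient averaging.** Note vectors are averaged (arithmetic mean)
   over all of the patient's notes, giving the patient vector that the
   classifiers consume.

The mean (rather than the sum) makes patients with different note volumes
comparable; it is order-invariant and invariant under duplicating the
whole note set, properties the tests assert. Notes with empty text
contribute zero vectors and still count in the mean's denominator: an
empty note is a real observation in which nothing was asserted.

## Sentence segmentation

No standard exists for clinical notes, and segmentation changes counts
(patterns never match across a boundary), so the rule is deliberately
simple, deterministic and auditable:

* hard boundaries at newlines;
* within a line, a run of `.?!` followed by whitespace (or end of line)
  terminates a sentence;
* a lone period is suppressed when the preceding token is a known
  abbreviation (`dr`, `mr`, `mrs`, `ms`, `pt`, `vs`, `st`, `jr`, `sr`,
  `prof`, `approx`, `dept`; case-insensitive).

Text with no sentence punctuation remains a single sentence, which keeps
long-range patterns (e.g. a bleeding→fibroid pattern spanning up to 750
characters) usable. A statistical segmenter would handle more
abbreviation and decimal edge cases but would make counts irreproducible
across versions; auditable determinism won.

## Matching semantics

* **Dialect:** Python `re`, which covers the Perl-style idioms clinical
  feature lists use (`\b`, `\w`, `\W`, `\s`, `{m,n}`, alternation,
  optional groups). Patterns that fail to compile raise immediately with
  the feature name and the compiler diagnostic — malformed patterns in a
  circulated feature list (a bad escape, an unterminated character class)
  must surface, not be silently accepted. One caveat the tests document:
  an unterminated `[` embedded in a longer alternation can be absorbed by
  a later `]` and *compile* with corrupted meaning; such typos are only
  detectable at the granularity of the broken fragment.
* **Case:** case-sensitive by default, because feature authors encode
  case deliberately (`(D|d)iabetes`, `(s|S)itus`); per-feature
  `case_sensitive: false` override.
* **Counting:** non-overlapping, leftmost-first scan. Overlapping
  counting was rejected because it double-counts nested alternations and
  has no obvious clinical meaning.
* **Negation** is handled entirely through user-authored patterns
  ("denies pelvic pain" as its own feature), not through a linguistic
  negation detector; this keeps the feature space interpretable by the
  clinician who authored it.

## Classifiers and confidence

Four families behind one interface: linear SVM, Gaussian naive Bayes,
decision tree, random forest (defaults: 100 trees; SVM C=1, L2; trees
unlimited depth). Confidence is defined as the probability of the
predicted class. NB, trees and forests expose probabilities natively; the
linear SVM's margins are mapped through a sigmoid (Platt) transform
fitted on the training data, so all four satisfy the same contract. Ties
in the score vector break toward the earlier class name in sorted order —
documented, deterministic, and exercised by a test.

Feature scaling: per-feature standardization is applied inside the SVM
pipeline only (fitted on training folds); NB and the tree models consume
raw mean counts, whose scale they are indifferent to.

Cross-validation is at the patient level by construction (vectors are
per-patient), so one patient's notes can never appear on both sides of a
fold. Methods: k-fold, stratified k-fold (default, 10 folds — the
conventional evaluation setting for this kind of study), leave-one-out.
Every stochastic step is seeded; identical data + config + seeds
reproduce reports byte-for-byte, and each CLI run writes a manifest
(config hash, seeds, library versions, deliberately no timestamps) that
pins the rerun.

Multi-class problems are supported natively; evaluation reports
one-vs-rest metrics per class, and the tests verify that collapsing a
multi-class result to target-vs-rest reproduces the dedicated binary
computation.

## Blinded evaluation

A held-out set is wrapped so that predictions can be made while the label
map is sealed; any metric computation before the explicit `unblind()`
call raises. Unblinding is idempotent and logged once. This mirrors the
intended workflow: iterate features on the training corpus only, then
score the held-out set exactly once.

## Metrics

Accuracy, per-class sensitivity, specificity, PPV, NPV, F1 from the
confusion matrix; AUROC from scores via the rank statistic (ties half
credit), macro-averaged one-vs-rest when there are more than two classes.
Zero-denominator ratios are reported as NaN with an explanatory note —
reporting 0 would misstate performance (e.g. NPV when nothing is
predicted negative). Out-of-fold accuracy (training iterations) and
held-out accuracy (after unblinding) are labeled distinctly in reports.

## Synthetic corpus generator

The generator emulates only the statistical structure the classifier
consumes — class-dependent planted phrases, negated surface forms,
near-miss decoys, neutral filler — and makes no attempt at realistic
clinical narrative. Consequences for interpretation: passing benchmarks
demonstrates the pipeline's mechanics (counting, aggregation, learning,
calibration of the evaluation machinery), not performance on real notes,
where misspellings, templated boilerplate, copy-forward text and richer
negation would lower accuracy.

Construction and verification:

* every planted phrase occupies its own sentence, so phrases cannot
  combine into accidental cross-phrase matches;
* positive phrases are verified at generation time to match their
  feature; decoys are verified to match *no* feature; every filler
  sentence is verified match-free before emission. Violations raise
  rather than silently corrupting the ground truth;
* ground-truth counts are assembled analytically from per-phrase match
  vectors, and the tests re-derive them with the feature engine on every
  generated corpus (exact equality).

Default shape parameters: 3–6 notes per patient, 4–8 sentences per note —
note-rich extracts of short notes, consistent with pulling all notes for
a patient over a study window. Scenario conditions:

* **balanced** (easy): 2 × 25 patients, signal-feature emission 0.3
  (case) vs 0.01 (control) per sentence slot, plus one neutral noise
  feature at 0.05 for both. At these rates an average patient has ~20–25
  sentence slots, so case and contaminated-control mean counts separate
  cleanly — the scenario is separable by design.
* **imbalanced** (moderate): 10 cases vs 100 controls (~1:10, the shape
  of rare-disease one-vs-rest studies), weak case signal (emission
  0.06/0.10 on two features, controls 0/0.02), 1–3 notes per patient.
  High specificity is cheap here while sensitivity degrades — the
  qualitative pattern of rare-phenotype screening.
* **negation**: both classes emit the pelvic-pain concept at rate 0.3;
  the symptomatic class always affirms, the asymptomatic class always
  negates. With the negation-aware feature pair the classes are
  separable; with the keyword alone they are statistically identical, so
  keyword-only accuracy sits at chance. The per-class negation-rate
  override exists precisely to express this scenario.

## Numerical and degenerate-input choices

* Stratified splitting allocates round-half-up `fraction × n_class` per
  class, clamped so both sides stay nonempty; classes with fewer than 2
  patients refuse to split.
* Unlabeled patients are first-class for prediction but block splitting,
  training and cross-validation with explicit errors.
* Conflicting labels within one patient are a hard validation error, not
  a majority vote.
* A single label per run is assumed; multi-phenotype studies run once per
  phenotype.

## Known limitations

* Regex dialect is Python `re`; feature lists authored against engines
  with possessive quantifiers or recursion would need rewriting.
* The abbreviation list is short and English-specific.
* The SVM sigmoid calibration is fitted on the same data that fitted the
  margin, which can make its probabilities optimistic on tiny training
  sets; forests and NB are unaffected.
* AUROC for more than two classes is macro one-vs-rest; other
  multi-class generalizations exist and give different numbers.
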