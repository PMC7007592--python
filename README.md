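# phenotext

Computable phenotyping from free-text clinical notes, for clinical and
translational researchers who need to classify patients (case vs noncase,
symptomatic vs asymptomatic, disease subtypes) when the deciding evidence
lives in notes rather than in structured EHR fields.

The design keeps the human expert in the loop: a clinician authors a small
set of named regular expressions — both presence patterns like
`(D|d)iabetes` and negation patterns like `(denies|no).{0,35}pelvic pain` —
and the library turns each patient's notes into one numeric vector that
standard classifiers can learn from.

## The model

For a patient with notes $d_1, \dots, d_m$ and features $f_1, \dots, f_K$,
each note is segmented into sentences and, for every sentence $s$,
$c_k(s)$ = number of non-overlapping matches of feature $f_k$ in $s$.
Counts are summed within a note and averaged across the patient's notes:

$$x_k(d) = \sum_{s \in d} c_k(s), \qquad \bar{x}_k = \frac{1}{m}\sum_{i=1}^{m} x_k(d_i)$$

The patient vector $\bar{x} \in \mathbb{R}^K$ is the unit of
classification. Four classifier families share one contract on these
vectors — linear SVM, Gaussian naive Bayes, decision tree, random forest —
and every prediction carries per-class probabilities, so a confidence
cutoff can route low-confidence patients to manual chart review.
Evaluation supports k-fold / stratified / leave-one-out cross-validation,
a blinded held-out workflow (labels sealed until an explicit, logged
unblind step), and the standard diagnostics: sensitivity, specificity,
PPV, NPV, F1, and AUROC.

A synthetic-corpus generator plants class-dependent phrases (with negated
surface forms and near-miss decoys) into filler text, with exact,
generation-time-verified ground-truth match counts, so the whole pipeline
is testable without access to real EHR data.

## Worked example

Generate a synthetic "symptomatic vs asymptomatic" corpus in which the two
classes mention *pelvic pain* equally often but the asymptomatic class
always negates it ("denies any pelvic pain today"), then cross-validate a
random forest with a negation-aware feature set:

```sh
phenotext generate --scenario negation --seed 7 --out-dir demo/data
phenotext train-cv --corpus demo/data/corpus.json \
    --features demo/data/features.json --folds 10 --seed 7 --out-dir demo/run
```

```
n evaluated: 50   abstained: 0
accuracy: 1.000
AUROC: 1.000
confusion matrix (rows=true, cols=predicted):
              asymptomatic   symptomatic
asymptomatic            25             0
symptomatic              0            25
```

All 50 patients are classified correctly out-of-fold: the two features
(`pelvic pain` and `(denies|no).{0,35}pelvic pain`) jointly separate the
classes. Rerunning with the keyword-only contrast set
(`demo/data/features_keyword_only.json`) collapses to chance — the single
keyword matches inside the negated sentences too:

```
n evaluated: 50   abstained: 0
accuracy: 0.520
AUROC: 0.493
```

This is the practical argument for authoring negation patterns alongside
keyword patterns. The run directory also contains per-patient out-of-fold
predictions with confidences (`oof_predictions.csv`), a review export
sorted by confidence (`misclassification_review.csv`), the fitted model,
and a run manifest; `phenotext evaluate` + `phenotext unblind` apply a
saved model to a held-out corpus with labels sealed until scoring.

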