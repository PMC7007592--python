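"""Confusion matrices, diagnostic metrics, blinding, and confidence cutoffs."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from phenotext import (
    BlindingError,
    ModelConfig,
    PatientVector,
    Prediction,
    compute_metrics,
    confidence_curve,
    confidence_filter,
    confusion,
    evaluate_blinded,
    make_blinded,
    metrics_after_unblinding,
    train,
)

from conftest import separable_vectors


def _pred(pid, label, conf, other="other"):
    return Prediction(pid, label, conf, {label: conf, other: 1 - conf})


def pairwise_auroc(y, s):
    """All-pairs concordance: P(positive outranks negative), ties half credit."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"])
        assert np.array_equal(cm.counts, np.array([[2, 0], [0, 1]]))

    def test_single_predicted_class_single_column(self):
        cm = confusion(["a", "b", "b"], ["a", "a", "a"])
        assert cm.counts[:, cm.class_names.index("a")].sum() == 3
        assert cm.counts[:, cm.class_names.index("b")].sum() == 0

    def test_matches_hand_tally_on_random_labels(self):
        rng = np.random.default_rng(11)
        classes = ["x", "y", "z"]
        y_true = [classes[i] for i in rng.integers(0, 3, 50)]
        y_pred = [classes[i] for i in rng.integers(0, 3, 50)]
        cm = confusion(y_true, y_pred)
        tally = Counter(zip(y_true, y_pred))
        for (t, p), n in tally.items():
            assert cm.counts[cm.class_names.index(t), cm.class_names.index(p)] == n
        assert cm.total == 50

    def test_unseen_predicted_label_rejected(self):
        with pytest.raises(ValueError, match="never seen"):
            confusion(["a", "a", "b"], ["a", "c", "b"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(["a", "b"], ["a"])


class TestMetrics:
    def test_sensitivity_specificity_from_printed_counts(self):
        # TP=90 FN=10 / FP=2 TN=98, "pos" treated one-vs-rest
        cm = confusion(["pos"] * 100 + ["neg"] * 100, ["pos"] * 90 + ["neg"] * 10 + ["pos"] * 2 + ["neg"] * 98)
        rep = compute_metrics(cm)
        assert rep.per_class["pos"]["sensitivity"] == pytest.approx(0.90)
        assert rep.per_class["pos"]["specificity"] == pytest.approx(0.98)
        assert rep.per_class["pos"]["ppv"] == pytest.approx(90 / 92)
        assert rep.accuracy == pytest.approx(188 / 200)

    def test_zero_denominator_reported_as_nan_not_zero(self):
        # everything predicted positive: NPV undefined
        cm = confusion(["pos", "pos", "neg"], ["pos", "pos", "pos"])
        rep = compute_metrics(cm)
        assert math.isnan(rep.per_class["pos"]["npv"])
        assert any("npv" in n for n in rep.notes)

    def test_perfectly_separating_scores_give_auroc_one(self):
        y = ["neg", "neg", "pos", "pos"]
        cm = confusion(y, y)
        scores = [{"pos": s, "neg": 1 - s} for s in (0.1, 0.2, 0.8, 0.9)]
        rep = compute_metrics(cm, y_true=y, scores=scores)
        assert rep.auroc == pytest.approx(1.0)

    def test_auroc_equals_all_pairs_concordance_on_fixed_lists(self):
        y = ["pos", "neg", "pos", "neg", "pos", "neg"]
        s = [0.9, 0.8, 0.8, 0.3, 0.4, 0.4]
        cm = confusion(y, ["pos"] * 6)
        rep = compute_metrics(cm, y_true=y, scores=[{"pos": v, "neg": 1 - v} for v in s])
        oracle = pairwise_auroc([1 if t == "pos" else 0 for t in y], s)
        assert rep.auroc == pytest.approx(oracle)

    def test_auroc_omitted_without_scores(self):
        cm = confusion(["a", "b"], ["a", "b"])
        assert compute_metrics(cm).auroc is None

    def test_metrics_agree_with_independent_formulas_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            k = int(rng.integers(2, 5))
            classes = [f"c{i}" for i in range(k)]
            # every class occurs at least once among the true labels so all
            # predicted labels are legal
            y_true = list(classes)
            y_pred = [classes[int(rng.integers(k))] for _ in classes]
            for _ in range(int(rng.integers(k, 60))):
                y_true.append(classes[int(rng.integers(k))])
                y_pred.append(classes[int(rng.integers(k))])
            cm = confusion(y_true, y_pred)
            rep = compute_metrics(cm)
            n = len(y_true)
            assert rep.accuracy == pytest.approx(
                sum(t == p for t, p in zip(y_true, y_pred)) / n
            )
            for cls in classes:
                tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
                fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
                fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
                tn = n - tp - fp - fn
                m = rep.per_class[cls]
                for got, num, den in (
                    (m["sensitivity"], tp, tp + fn),
                    (m["specificity"], tn, tn + fp),
                    (m["ppv"], tp, tp + fp),
                    (m["npv"], tn, tn + fn),
                ):
                    if den == 0:
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(num / den)

    def test_binary_collapse_matches_dedicated_binary_metrics(self):
        # one-vs-rest on a 3-class problem == binary metrics after collapsing
        rng = np.random.default_rng(3)
        classes = ["pcd", "cf", "control"]
        y_true = [classes[i] for i in rng.integers(0, 3, 80)]
        y_pred = [classes[i] for i in rng.integers(0, 3, 80)]
        multi = compute_metrics(confusion(y_true, y_pred))
        yt = ["pcd" if t == "pcd" else "rest" for t in y_true]
        yp = ["pcd" if p == "pcd" else "rest" for p in y_pred]
        binary = compute_metrics(confusion(yt, yp))
        for key in ("sensitivity", "specificity", "ppv", "npv", "f1"):
            a, b = multi.per_class["pcd"][key], binary.per_class["pcd"][key]
            assert (math.isnan(a) and math.isnan(b)) or a == pytest.approx(b)


class TestConfidenceCutoff:
    def test_filter_partitions_at_threshold(self):
        preds = [_pred("p1", "a", 0.9), _pred("p2", "a", 0.5), _pred("p3", "a", 0.6)]
        accepted, abstained = confidence_filter(preds, 0.55)
        assert [p.patient_id for p in accepted] == ["p1", "p3"]
        assert [p.patient_id for p in abstained] == ["p2"]
        assert len(accepted) + len(abstained) == len(preds)

    def test_cutoff_zero_accepts_all_and_one_abstains_all(self):
        preds = [_pred("p1", "a", 0.9), _pred("p2", "a", 0.51)]
        assert len(confidence_filter(preds, 0.0)[0]) == 2
        assert len(confidence_filter(preds, 1.0)[1]) == 2

    def test_curve_n_accepted_non_increasing(self):
        rng = np.random.default_rng(9)
        preds = [_pred(f"p{i}", "a", float(c)) for i, c in enumerate(rng.uniform(0.5, 1, 40))]
        truth = {p.patient_id: "a" if rng.random() < 0.8 else "b" for p in preds}
        curve = confidence_curve(preds, truth)
        assert (np.diff(curve["n_accepted"]) <= 0).all()

    def test_all_correct_gives_accuracy_one_everywhere(self):
        preds = [_pred(f"p{i}", "a", 0.5 + i / 10) for i in range(5)]
        truth = {p.patient_id: "a" for p in preds}
        curve = confidence_curve(preds, truth)
        assert (curve["accuracy_on_accepted"] == 1.0).all()


class TestBlinding:
    @pytest.fixture
    def setup(self):
        vecs = separable_vectors()
        model = train(vecs, ModelConfig("gaussian_nb"))
        blinded = make_blinded(vecs)
        return model, blinded

    def test_predictions_possible_but_labels_sealed(self, setup):
        model, blinded = setup
        preds = evaluate_blinded(model, blinded)
        assert len(preds) == 20
        assert all(v.label is None for v in blinded.vectors)
        with pytest.raises(BlindingError):
            blinded.labels()

    def test_unblind_then_metrics(self, setup):
        model, blinded = setup
        preds = evaluate_blinded(model, blinded)
        rep = metrics_after_unblinding(blinded, preds)
        assert rep.accuracy == 1.0
        assert blinded.is_unblinded

    def test_double_unblind_is_idempotent_with_single_log_entry(self, setup):
        _, blinded = setup
        first = blinded.unblind()
        second = blinded.unblind()
        assert first == second
        assert len(blinded.log) == 1

    def test_unlabeled_vectors_cannot_be_sealed(self):
        vecs = [PatientVector("p1", (0.0,), 1, None)]
        with pytest.raises(ValueError, match="unlabeled"):
            make_blinded(vecs)
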