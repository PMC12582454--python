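"""Metric definitions cross-checked against brute force and scikit-learn."""
import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import (cohen_kappa_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from rntnet.metrics import (classification_metrics, confusion_matrix,
                            paired_t_test, per_class_kappa, roc_auc)


def test_confusion_matrix_hand_count():
    cm = confusion_matrix([0, 0, 1, 2], [0, 1, 1, 2], 3)
    expected = np.zeros((3, 3), np.int64)
    expected[0, 0] = expected[0, 1] = expected[1, 1] = expected[2, 2] = 1
    np.testing.assert_array_equal(cm, expected)
    assert cm.sum() == 4  # conservation


def test_confusion_matrix_rejects_out_of_range_labels():
    with pytest.raises(ValueError, match="outside"):
        confusion_matrix([0, 3], [0, 1], 3)


def test_perfect_predictions_give_diagonal_and_unit_metrics(rng):
    y = rng.integers(0, 4, 50)
    cm = confusion_matrix(y, y, 4)
    assert (cm == np.diag(np.diag(cm))).all()
    m = classification_metrics(cm)
    for v in (m.accuracy, m.precision, m.recall, m.f1, m.kappa):
        assert v == pytest.approx(1.0)


def test_chance_agreement_gives_zero_kappa():
    m = classification_metrics(np.array([[25, 25], [25, 25]]))
    assert m.accuracy == pytest.approx(0.5)
    assert m.kappa == pytest.approx(0.0, abs=1e-12)


def test_binary_aggregate_accuracy_from_counts():
    # TP 3135, TN 3065, FP 61, FN 58 -> 6200 / 6319
    cm = np.array([[3065, 61], [58, 3135]])
    m = classification_metrics(cm)
    assert m.accuracy == pytest.approx(6200 / 6319, abs=1e-12)
    assert m.accuracy == pytest.approx(0.98117, abs=5e-6)


def test_metrics_match_definitional_brute_force_on_random_matrices():
    """Accuracy/precision/recall/F1/kappa on 100 random confusion matrices
    agree with an independent definitional computation to 1e-10."""
    rng = np.random.default_rng(123)
    for _ in range(100):
        k = int(rng.integers(2, 7))
        cm = rng.integers(0, 40, (k, k)).astype(float)
        cm[rng.integers(0, k), rng.integers(0, k)] += 1  # non-empty
        with np.errstate(all="ignore"):
            m = classification_metrics(cm)
        total = cm.sum()
        acc = np.trace(cm) / total
        prec, rec, f1 = [], [], []
        for c in range(k):
            tp = cm[c, c]
            p = tp / cm[:, c].sum() if cm[:, c].sum() else 0.0
            r = tp / cm[c, :].sum() if cm[c, :].sum() else 0.0
            prec.append(p)
            rec.append(r)
            f1.append(2 * p * r / (p + r) if p + r else 0.0)
        pe = sum(cm[c, :].sum() * cm[:, c].sum() for c in range(k)) / total ** 2
        kappa = (acc - pe) / (1 - pe) if pe != 1 else 0.0
        assert abs(m.accuracy - acc) < 1e-10
        assert abs(m.precision - np.mean(prec)) < 1e-10
        assert abs(m.recall - np.mean(rec)) < 1e-10
        assert abs(m.f1 - np.mean(f1)) < 1e-10
        assert abs(m.kappa - kappa) < 1e-10


def test_metrics_agree_with_sklearn_from_labels(rng):
    y_true = rng.integers(0, 5, 300)
    y_pred = rng.integers(0, 5, 300)
    m = classification_metrics(confusion_matrix(y_true, y_pred, 5))
    assert m.precision == pytest.approx(
        precision_score(y_true, y_pred, average="macro", zero_division=0))
    assert m.recall == pytest.approx(
        recall_score(y_true, y_pred, average="macro", zero_division=0))
    assert m.f1 == pytest.approx(
        f1_score(y_true, y_pred, average="macro", zero_division=0))
    assert m.kappa == pytest.approx(cohen_kappa_score(y_true, y_pred))


def test_accuracy_is_prevalence_weighted_mean_of_recalls(rng):
    for _ in range(20):
        cm = rng.integers(0, 30, (4, 4)).astype(float) + np.eye(4)
        m = classification_metrics(cm)
        prev = cm.sum(axis=1) / cm.sum()
        np.testing.assert_allclose(
            m.accuracy, (prev * np.asarray(m.per_class["recall"])).sum(),
            atol=1e-12)


def test_macro_f1_bounded_by_per_class_extremes(rng):
    for _ in range(20):
        cm = rng.integers(0, 30, (5, 5)).astype(float) + np.eye(5)
        m = classification_metrics(cm)
        f1s = np.asarray(m.per_class["f1"])
        assert f1s.min() - 1e-12 <= m.f1 <= f1s.max() + 1e-12


def test_kappa_near_zero_under_label_permutation(rng):
    y = np.repeat(np.arange(4), 250)
    pred = rng.permutation(y)
    m = classification_metrics(confusion_matrix(y, pred, 4))
    assert abs(m.kappa) < 0.05


def test_empty_class_column_warns_and_defines_zero():
    cm = np.array([[5, 0, 0], [3, 0, 0], [0, 0, 2]])
    with pytest.warns(UserWarning, match="empty class"):
        m = classification_metrics(cm)
    assert m.per_class["precision"][1] == 0.0


# -- ROC / AUC ---------------------------------------------------------------


def test_perfectly_separating_scores_give_auc_one():
    y = np.array([1, 0, 1])
    scores = np.column_stack([1 - np.array([0.9, 0.1, 0.8]),
                              np.array([0.9, 0.1, 0.8])])
    assert roc_auc(y, scores)["per_class"][1] == pytest.approx(1.0)


def test_random_scores_give_auc_half():
    rng = np.random.default_rng(9)
    y = rng.integers(0, 2, 2000)
    s = rng.random(2000)
    scores = np.column_stack([1 - s, s])
    out = roc_auc(y, scores)
    assert abs(out["per_class"][1] - 0.5) < 0.03


def test_auc_invariant_under_monotone_transform(rng):
    y = rng.integers(0, 3, 120)
    raw = rng.random((120, 3))
    scores = raw / raw.sum(axis=1, keepdims=True)
    a = roc_auc(y, scores)
    b = roc_auc(y, np.exp(3 * scores))  # strictly monotone transform
    np.testing.assert_allclose(a["per_class"], b["per_class"], atol=1e-12)


def test_single_class_truth_rejected():
    with pytest.raises(ValueError, match="two classes"):
        roc_auc(np.zeros(5, int), np.random.rand(5, 2))


# -- paired t-test -----------------------------------------------------------


def test_symmetric_differences_give_zero_t_and_p_one():
    b = np.zeros(8)
    a = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
    r = paired_t_test(a, b)
    assert r.mean_difference == pytest.approx(0.0)
    assert r.t_statistic == pytest.approx(0.0)
    assert r.p_value == pytest.approx(1.0)


def test_identical_samples_raise_degenerate_error():
    a = np.arange(8, dtype=float)
    with pytest.raises(ValueError, match="zero-variance"):
        paired_t_test(a, a.copy())


def test_t_statistic_matches_reference_t_distribution():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    b = np.array([2.0, 3.0, 5.0, 4.0])
    r = paired_t_test(a, b)
    # independent closed-form check: t = mean(d) / (sd(d)/sqrt(n))
    d = a - b
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t), len(d) - 1)
    assert r.t_statistic == pytest.approx(t, abs=1e-6)
    assert r.p_value == pytest.approx(p, abs=1e-6)
    assert r.n_pairs == 4


def test_per_class_kappa_matches_sklearn_one_vs_rest(rng):
    y_true = rng.integers(0, 4, 200)
    y_pred = rng.integers(0, 4, 200)
    ours = per_class_kappa(y_true, y_pred, 4)
    for c in range(4):
        ref = cohen_kappa_score((y_true == c).astype(int),
                                (y_pred == c).astype(int))
        assert ours[c] == pytest.approx(ref, abs=1e-12)


def test_micro_auc_matches_sklearn_ovr(rng):
    y = rng.integers(0, 4, 200)
    raw = rng.random((200, 4))
    scores = raw / raw.sum(axis=1, keepdims=True)
    out = roc_auc(y, scores)
    onehot = np.eye(4)[y]
    assert out["micro"] == pytest.approx(
        roc_auc_score(onehot.ravel(), scores.ravel()))
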